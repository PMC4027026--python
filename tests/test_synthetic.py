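import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memspec import binding as bd
from memspec import synthetic as syn
from memspec.errors import RangeError


class TestPakeGenerator:
    def test_horn_separation_matches_splitting(self):
        # the 90° horns of a 4 kHz doublet sit at ±2 kHz; the argmax of the
        # broadened pattern shifts inward by a fraction of the line width
        s = syn.simulate_pake_spectrum([syn.PakeComponent(4.0, 1.0, "CD3")],
                                       broadening_khz=0.05, axis_range_khz=10.0,
                                       n_points=4096)
        pos = s.axis[s.axis > 0]
        horn_hi = pos[np.argmax(s.intensity[s.axis > 0])]
        neg = s.axis[s.axis < 0]
        horn_lo = neg[np.argmax(s.intensity[s.axis < 0])]
        assert horn_hi - horn_lo == pytest.approx(4.0, abs=0.05 + 3 * s.step)

    def test_shoulders_extend_to_full_splitting(self):
        # 0° shoulders at ±Δ: intensity above 1% of max just inside ±Δ,
        # negligible beyond the broadening tails
        delta = 12.0
        s = syn.simulate_pake_spectrum([syn.PakeComponent(delta, 1.0)],
                                       broadening_khz=0.2, axis_range_khz=20.0,
                                       n_points=4096)
        inside = (np.abs(s.axis) > 0.9 * delta) & (np.abs(s.axis) < delta)
        outside = np.abs(s.axis) > delta + 1.5
        assert s.intensity[inside].max() > 0.01 * s.intensity.max()
        assert s.intensity[outside].max() < 0.005 * s.intensity.max()

    def test_noiseless_spectrum_is_symmetric(self):
        comps = syn.dmpc_d54_fixture("DMPC", 298.0)
        s = syn.simulate_pake_spectrum(comps, axis_range_khz=45.0, n_points=2048)
        asym = np.max(np.abs(s.intensity - s.intensity[::-1]))
        assert asym < 1e-6 * s.intensity.max()

    def test_total_intensity_linear_in_weights(self):
        c1 = [syn.PakeComponent(8.0, 1.0), syn.PakeComponent(20.0, 2.0)]
        c3 = [syn.PakeComponent(8.0, 3.0), syn.PakeComponent(20.0, 6.0)]
        s1 = syn.simulate_pake_spectrum(c1, axis_range_khz=30.0, n_points=1024)
        s3 = syn.simulate_pake_spectrum(c3, axis_range_khz=30.0, n_points=1024)
        np.testing.assert_allclose(s3.intensity, 3.0 * s1.intensity, rtol=0, atol=1e-6)

    def test_zero_components_gives_flat_baseline(self):
        s = syn.simulate_pake_spectrum([], noise_sd=0.01, seed=1, n_points=512)
        assert np.abs(np.mean(s.intensity)) < 0.01

    def test_seeded_noise_is_deterministic(self):
        a = syn.simulate_pake_spectrum([syn.PakeComponent(5.0, 1.0)], noise_sd=0.1,
                                       seed=9, n_points=512)
        b = syn.simulate_pake_spectrum([syn.PakeComponent(5.0, 1.0)], noise_sd=0.1,
                                       seed=9, n_points=512)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_narrow_axis_raises_range_error(self):
        with pytest.raises(RangeError):
            syn.simulate_pake_spectrum([syn.PakeComponent(30.0, 1.0)],
                                       axis_range_khz=20.0)


class TestDmpcFixture:
    @pytest.mark.parametrize(
        "system,cd3,plateau",
        [
            ("DMPC", 4.0, 29.0),
            ("DMPC+CYSP", 4.2, 31.0),
            ("DMPC+POLYA", 3.6, 26.6),
            ("DMPC+ASD", 4.4, 28.0),
        ],
    )
    def test_endpoint_splittings(self, system, cd3, plateau):
        comps = syn.dmpc_d54_fixture(system, 298.0)
        by_label = {c.label: c for c in comps}
        assert by_label["CD3"].splitting_90 == pytest.approx(cd3)
        assert by_label["plateau"].splitting_90 == pytest.approx(plateau)
        assert by_label["CD3"].weight == 6.0
        assert by_label["plateau"].weight == 28.0
        assert len(comps) == 8

    def test_intermediates_monotone(self):
        comps = syn.dmpc_d54_fixture("DMPC", 298.0)
        values = [c.splitting_90 for c in comps]
        assert values == sorted(values)

    def test_unknown_system_rejected(self):
        with pytest.raises(ValueError):
            syn.dmpc_d54_fixture("DPPC", 298.0)
        with pytest.raises(ValueError):
            syn.dmpc_d54_fixture("DMPC", 300.0)


class TestCsaGenerator:
    def test_edge_separation_is_csa(self):
        # the 2% support must bracket the tensor edges and may exceed them
        # only by broadening tails
        s = syn.simulate_csa_powder(syn.CsaModel(csa=58.0, broadening=0.3),
                                    n_points=4096)
        thr = 0.02 * s.intensity.max()
        support = s.axis[s.intensity > thr]
        width = support[-1] - support[0]
        assert 58.0 - 0.5 <= width <= 58.0 + 3.0

    def test_perpendicular_edge_is_maximum(self):
        s = syn.simulate_csa_powder(syn.CsaModel(csa=58.0, iso_position=0.0,
                                                 broadening=0.5), n_points=2048)
        # σ⊥ = iso + csa/3
        assert s.axis[np.argmax(s.intensity)] == pytest.approx(58.0 / 3, abs=1.0)

    def test_zero_csa_collapses_to_single_line(self):
        s = syn.simulate_csa_powder(syn.CsaModel(csa=0.0, iso_position=2.0,
                                                 broadening=0.5), n_points=1024)
        assert s.axis[np.argmax(s.intensity)] == pytest.approx(2.0, abs=0.1)

    def test_600hz_isotropic_line_visible_at_iso(self):
        model = syn.CsaModel(csa=58.0, broadening=1.0,
                             isotropic_components=[(0.0, 600.0, 0.5)])
        with_line = syn.simulate_csa_powder(model, n_points=2048)
        without = syn.simulate_csa_powder(syn.CsaModel(csa=58.0, broadening=1.0),
                                          n_points=2048)
        i0 = np.argmin(np.abs(with_line.axis))
        assert with_line.intensity[i0] > 3.0 * without.intensity[i0]


class TestEsrGenerator:
    def test_derivative_extrema_separations(self):
        s = syn.simulate_esr_spectrum(syn.EsrModel(60.0, 20.0), n_points=4096)
        maxima = s.axis[np.argmax(s.intensity)]
        minima = s.axis[np.argmin(s.intensity)]
        # global extrema are the taller inner pair at ±T⊥
        assert minima - maxima == pytest.approx(20.0, abs=0.5)
        left = s.intensity[s.axis < s.metadata.get("center", 3480) - 15]
        outer_max = s.axis[: left.size][np.argmax(left)]
        assert outer_max == pytest.approx(3480 - 30.0, abs=0.5)

    def test_determinism_under_seed(self):
        a = syn.simulate_esr_spectrum(syn.EsrModel(60.0, 20.0), noise_sd=0.05, seed=4)
        b = syn.simulate_esr_spectrum(syn.EsrModel(60.0, 20.0), noise_sd=0.05, seed=4)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            syn.EsrModel(20.0, 60.0)


class TestTransitionSeries:
    def test_value_at_midpoint_is_mean_of_plateaus(self):
        gt = syn.TransitionGroundTruth(76.0, 58.0, 297.0, 0.8)
        table = syn.simulate_transition_series(gt, [290, 293, 295, 297, 299, 303, 310])
        at_mid = table.observable()[table.key_values == 297.0][0]
        assert at_mid == pytest.approx(67.0, abs=1e-9)

    def test_high_temperature_asymptote(self):
        gt = syn.TransitionGroundTruth(76.0, 58.0, 297.0, 0.5)
        table = syn.simulate_transition_series(gt, [290, 294, 296, 298, 300, 340])
        assert table.observable()[-1] == pytest.approx(58.0, abs=1e-9)

    def test_seeded_regeneration_identical(self):
        gt = syn.TransitionGroundTruth(1.0, 0.0, 297.0, 1.0)
        t = np.arange(290.0, 305.0)
        a = syn.simulate_transition_series(gt, t, noise_sd=0.05, seed=2)
        b = syn.simulate_transition_series(gt, t, noise_sd=0.05, seed=2)
        np.testing.assert_array_equal(a.observable(), b.observable())


class TestJobSeriesGenerator:
    def test_bound_fraction_closed_form(self):
        # 1:1 quadratic at H0 = G0 = 1 mM, Kd = 10^-4.5 M: bound fraction 0.837
        gt = syn.BindingGroundTruth(log_ka=4.5, delta_free=0.0, delta_bound=0.10)
        series = syn.simulate_job_series(gt, [0.3, 0.4, 0.5, 0.6, 0.7])
        shift_at_half = series.shifts["H1"][2]
        assert shift_at_half / 0.10 == pytest.approx(0.8373, abs=5e-4)

    def test_saturation_limit_reaches_bound_shift(self):
        gt = syn.BindingGroundTruth(log_ka=12.0, delta_free=3.85, delta_bound=3.95)
        series = syn.simulate_job_series(gt, [0.25, 0.5, 0.75])
        assert series.shifts["H1"][1] == pytest.approx(3.95, abs=1e-4)

    def test_equal_shifts_give_flat_series(self):
        gt = syn.BindingGroundTruth(log_ka=4.5, delta_free=1.0, delta_bound=1.0)
        series = syn.simulate_job_series(gt, [0.2, 0.5, 0.8])
        np.testing.assert_allclose(series.shifts["H1"], 1.0, atol=1e-12)

    def test_fraction_bounds_enforced(self):
        gt = syn.BindingGroundTruth(log_ka=4.5)
        with pytest.raises(ValueError):
            syn.simulate_job_series(gt, [0.0, 0.5, 1.0])


class TestBindingModelProperties:
    @given(
        log_ka=st.floats(1.0, 8.0),
        h0=st.floats(1e-5, 1e-2),
        g0=st.floats(1e-5, 1e-2),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_by_limiting_reagent(self, log_ka, h0, g0):
        hg = bd.binding_model(h0, g0, log_ka)
        assert 0.0 <= hg <= min(h0, g0) + 1e-18

    @given(log_ka=st.floats(1.0, 7.5), h0=st.floats(1e-4, 5e-3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_affinity(self, log_ka, h0):
        assert bd.binding_model(h0, h0, log_ka + 0.5) >= bd.binding_model(h0, h0, log_ka)
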