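import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memspec import deuterium as deu
from memspec import synthetic as syn
from memspec.errors import (
    AlignmentError,
    AssignmentError,
    DegenerateInputError,
    RangeError,
)
from memspec.pipeline import fixture_spectrum


class TestOrderParameterArithmetic:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.0, 1.0), (90.0, -0.5), (54.7356, 0.0)],
    )
    def test_scd_from_angle(self, beta, expected):
        assert deu.scd_from_angle(beta) == pytest.approx(expected, abs=1e-6)

    @given(beta=st.floats(-360.0, 360.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scd_bounded(self, beta):
        assert -0.5 <= deu.scd_from_angle(beta) <= 1.0

    @pytest.mark.parametrize(
        "dnq,expected",
        [(0.0, 0.0), (29.0, 0.227451), (4.0, 0.0313725)],
    )
    def test_splitting_to_scd(self, dnq, expected):
        assert deu.order_parameter_from_splitting(dnq) == pytest.approx(expected, abs=1e-6)

    def test_scd_linear_in_splitting(self):
        assert deu.order_parameter_from_splitting(10.0) == pytest.approx(
            2 * deu.order_parameter_from_splitting(5.0)
        )

    def test_negative_splitting_rejected_and_large_warns(self):
        with pytest.raises(ValueError):
            deu.order_parameter_from_splitting(-1.0)
        with pytest.warns(UserWarning):
            deu.order_parameter_from_splitting(200.0)


class TestSymmetrize:
    def test_symmetric_input_unchanged(self, single_doublet_spectrum):
        out = deu.symmetrize(single_doublet_spectrum, 0.0)
        np.testing.assert_allclose(out.intensity, single_doublet_spectrum.intensity,
                                   atol=1e-9)
        assert out.metadata["asymmetry_fraction"] < 1e-6

    def test_odd_perturbation_removed(self, single_doublet_spectrum):
        s = single_doublet_spectrum
        odd = 0.01 * np.sin(s.axis)
        with pytest.warns(UserWarning):
            out = deu.symmetrize(s.replace(intensity=s.intensity + odd), 0.0)
        np.testing.assert_allclose(out.intensity, s.intensity, atol=1e-9)

    def test_center_outside_axis_rejected(self, single_doublet_spectrum):
        with pytest.raises(Exception):
            deu.symmetrize(single_doublet_spectrum, 100.0)


class TestDepake:
    def test_single_doublet_mode_recovered(self, single_doublet_spectrum):
        dist = deu.depake(single_doublet_spectrum, lam=1e-6,
                          grid_min=1.0, grid_max=18.0, grid_step=0.1)
        comps = deu.extract_splittings(dist)
        assert comps[0][0] == pytest.approx(10.0, abs=0.1)

    def test_noiseless_forward_residual_small(self, single_doublet_spectrum):
        dist = deu.depake(single_doublet_spectrum, lam=1e-8,
                          grid_min=1.0, grid_max=18.0, grid_step=0.1)
        assert dist.residual < 1e-3

    def test_dmpc_fixture_all_positions_recovered(self):
        s = fixture_spectrum("DMPC", 298.0, snr=100.0, seed=7)
        comps = deu.extract_splittings(deu.depake(s), max_components=8)
        truth = [c.splitting_90 for c in syn.dmpc_d54_fixture("DMPC", 298.0)]
        got = sorted(c[0] for c in comps)
        assert len(got) == 8
        for t, g in zip(truth, got):
            assert g == pytest.approx(t, abs=0.4)

    def test_zero_spectrum_is_degenerate(self, single_doublet_spectrum):
        zero = single_doublet_spectrum.replace(
            intensity=np.zeros_like(single_doublet_spectrum.intensity)
        )
        with pytest.raises(DegenerateInputError):
            deu.depake(zero)

    def test_grid_beyond_axis_rejected(self, single_doublet_spectrum):
        with pytest.raises(RangeError):
            deu.depake(single_doublet_spectrum, grid_max=40.0)

    def test_round_trip_random_component_sets(self):
        # 20 random membranes: every true splitting recovered within
        # max(0.5 kHz, grid step) and no spurious component above 10% weight
        rng = np.random.default_rng(2024)
        for _ in range(20):
            n = int(rng.integers(2, 10))
            while True:
                sp = np.sort(rng.uniform(2.0, 35.0, n))
                if np.all(np.diff(sp) >= 2.0):
                    break
            comps = [syn.PakeComponent(float(v), float(w))
                     for v, w in zip(sp, rng.uniform(0.5, 3.0, n))]
            broad = float(rng.uniform(0.2, 1.0))
            clean = syn.simulate_pake_spectrum(comps, broadening_khz=broad,
                                               axis_range_khz=45.0, n_points=2048)
            noise = np.max(np.abs(clean.intensity)) / float(rng.uniform(50, 200))
            s = syn.simulate_pake_spectrum(comps, broadening_khz=broad,
                                           axis_range_khz=45.0, n_points=2048,
                                           noise_sd=noise,
                                           seed=int(rng.integers(0, 2**31)))
            got = deu.extract_splittings(deu.depake(s), max_components=n + 2)
            positions = [g for g, _ in got]
            max_w = max(w for _, w in got)
            for t in sp:
                assert any(abs(t - g) <= 0.5 for g in positions), (sp, positions)
            for g, w in got:
                if w > 0.1 * max_w:
                    assert any(abs(t - g) <= 0.5 for t in sp), (sp, positions)


class TestExtractSplittings:
    def test_unimodal_distribution(self):
        grid = np.arange(1.0, 30.0, 0.1)
        w = np.exp(-0.5 * ((grid - 10.0) / 0.2) ** 2)
        d = deu.SplittingDistribution(grid, w, 0.0, 0.0)
        comps = deu.extract_splittings(d)
        assert len(comps) == 1
        assert comps[0][0] == pytest.approx(10.0, abs=0.1)

    def test_close_peaks_merge_to_centroid(self):
        grid = np.arange(1.0, 30.0, 0.1)
        w = np.exp(-0.5 * ((grid - 10.0) / 0.1) ** 2) + np.exp(
            -0.5 * ((grid - 10.6) / 0.1) ** 2
        )
        comps = deu.extract_splittings(deu.SplittingDistribution(grid, w, 0.0, 0.0),
                                       min_separation_khz=1.0)
        assert len(comps) == 1
        assert comps[0][0] == pytest.approx(10.3, abs=0.15)

    def test_empty_distribution_warns(self):
        grid = np.arange(1.0, 5.0, 0.1)
        with pytest.warns(UserWarning):
            out = deu.extract_splittings(
                deu.SplittingDistribution(grid, np.zeros_like(grid), 0.0, 0.0)
            )
        assert out == []


class TestProfileAssignment:
    def test_two_splittings_assign_endpoints(self):
        prof = deu.assign_profile([4.0, 29.0], "DMPC", 298.0)
        assert prof.labels == ["CD3", "plateau"]
        assert prof.splitting("plateau") == 29.0

    def test_order_invariance(self):
        a = deu.assign_profile([29.0, 4.0], "DMPC", 298.0)
        b = deu.assign_profile([4.0, 29.0], "DMPC", 298.0)
        assert a.records == b.records

    def test_eight_component_labels(self):
        values = [c.splitting_90 for c in syn.dmpc_d54_fixture("DMPC", 298.0)]
        prof = deu.assign_profile(values, "DMPC", 298.0)
        assert prof.labels == ["CD3", "C14", "C13", "C12", "C11", "C10", "C9", "plateau"]

    def test_single_splitting_rejected(self):
        with pytest.raises(AssignmentError):
            deu.assign_profile([4.0], "DMPC", 298.0)


class TestRelativeFluidity:
    def test_identity_gives_zero(self):
        p = deu.assign_profile([4.0, 29.0], "DMPC", 298.0)
        rel = deu.relative_fluidity(p, p)
        assert all(v == 0.0 for v in rel.values.values())

    def test_published_endpoint_ratios(self):
        polya = deu.assign_profile([3.6, 26.6], "DMPC+POLYA", 298.0)
        asd = deu.assign_profile([4.4, 28.0], "DMPC+ASD", 298.0)
        ref = deu.assign_profile([4.0, 29.0], "DMPC", 298.0)
        rel_p = deu.relative_fluidity(polya, ref)
        rel_a = deu.relative_fluidity(asd, ref)
        assert rel_p.values["plateau"] == pytest.approx(-0.08276, abs=1e-5)
        assert rel_a.values["CD3"] == pytest.approx(0.10, abs=1e-9)
        assert rel_a.values["plateau"] == pytest.approx(-0.034483, abs=1e-6)

    def test_label_mismatch_rejected(self):
        a = deu.assign_profile([4.0, 10.0, 29.0], "X", 298.0)
        b = deu.assign_profile([4.0, 29.0], "DMPC", 298.0)
        with pytest.raises(AlignmentError):
            deu.relative_fluidity(a, b)
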