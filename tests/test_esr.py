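import numpy as np
import pytest

from memspec import esr
from memspec import phosphorus as ph
from memspec import synthetic as syn
from memspec.errors import UnitError


class TestMeasureHyperfine:
    def test_round_trip_60_20(self):
        s = syn.simulate_esr_spectrum(syn.EsrModel(60.0, 20.0), n_points=2048)
        m = esr.measure_hyperfine(s)
        assert m.two_T_par == pytest.approx(60.0, abs=0.5)
        assert m.two_T_perp == pytest.approx(20.0, abs=0.5)
        assert not m.unincorporated_probe

    def test_isotropic_triplet_flagged(self):
        s = syn.simulate_isotropic_esr_triplet()
        m = esr.measure_hyperfine(s)
        assert m.unincorporated_probe

    def test_smoothing_window_robustness(self):
        clean = syn.simulate_esr_spectrum(syn.EsrModel(60.0, 20.0), n_points=2048)
        noisy = syn.simulate_esr_spectrum(
            syn.EsrModel(60.0, 20.0), n_points=2048,
            noise_sd=np.max(np.abs(clean.intensity)) / 50, seed=8,
        )
        m5 = esr.measure_hyperfine(noisy, smoothing_window=5)
        m11 = esr.measure_hyperfine(noisy, smoothing_window=11)
        assert abs(m5.two_T_par - m11.two_T_par) < 0.5
        assert abs(m5.two_T_perp - m11.two_T_perp) < 0.5

    def test_invariant_under_translation_and_scaling(self):
        s = syn.simulate_esr_spectrum(syn.EsrModel(60.0, 20.0), n_points=2048)
        m0 = esr.measure_hyperfine(s)
        shifted = s.replace(axis=s.axis + 40.0)
        scaled = s.replace(intensity=s.intensity * 5.5)
        for m in (esr.measure_hyperfine(shifted), esr.measure_hyperfine(scaled)):
            assert m.two_T_par == pytest.approx(m0.two_T_par, abs=1e-9)
            assert m.two_T_perp == pytest.approx(m0.two_T_perp, abs=1e-9)

    def test_round_trip_random_draws(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            two_t_perp = float(rng.uniform(16.0, 26.0))
            two_t_par = float(rng.uniform(two_t_perp + 18.0, 68.0))
            model = syn.EsrModel(two_t_par, two_t_perp)
            clean = syn.simulate_esr_spectrum(model, n_points=2048)
            s = syn.simulate_esr_spectrum(
                model, n_points=2048,
                noise_sd=np.max(np.abs(clean.intensity)) / float(rng.uniform(30, 150)),
                seed=int(rng.integers(0, 2**31)),
            )
            m = esr.measure_hyperfine(s)
            assert m.two_T_par == pytest.approx(two_t_par, abs=0.5)
            assert m.two_T_perp == pytest.approx(two_t_perp, abs=0.5)

    def test_wrong_axis_unit_rejected(self, single_doublet_spectrum):
        with pytest.raises(UnitError):
            esr.measure_hyperfine(single_doublet_spectrum)


class TestOrderParameter:
    def test_matches_independent_arithmetic(self):
        # independent evaluation of the printed expression
        for two_par, two_perp in [(60.0, 20.0), (30.0, 29.999), (55.0, 21.0)]:
            t_par, t_perp = two_par / 2.0, two_perp / 2.0
            c = 1.4 - 0.053 * (t_par - t_perp)
            expected = 1.723 * (two_par - two_perp - c) / (t_par + two_perp + c)
            m = esr.HyperfineMeasurement(two_par, two_perp)
            got = esr.esr_order_parameter(m)
            assert abs(got.s - expected) < 1e-12
            assert abs(got.c_correction - c) < 1e-12

    def test_degenerate_splittings_value(self):
        # equal separations: C = 1.4 and S = 1.723·(−1.4)/46.4
        m = esr.HyperfineMeasurement(30.0, 30.0)
        got = esr.esr_order_parameter(m)
        assert got.c_correction == pytest.approx(1.4)
        assert got.s == pytest.approx(1.723 * (-1.4) / 46.4, abs=1e-12)

    def test_standard_form_bounded_for_typical_values(self):
        m = esr.HyperfineMeasurement(60.0, 20.0)
        got = esr.esr_order_parameter(m, form="standard")
        assert 0.0 < got.s < 1.0

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            esr.esr_order_parameter(esr.HyperfineMeasurement(60.0, 20.0), form="x")


class TestOrderTemperatureProfile:
    def spectra_series(self, midpoint=297.0, temps=None, snr=100.0, seed0=100):
        gt = syn.TransitionGroundTruth(62.0, 52.0, midpoint, 0.8)
        temps = np.arange(290.0, 310.5, 2.0) if temps is None else np.asarray(temps)
        pairs = []
        for i, t in enumerate(temps):
            model = syn.EsrModel(float(syn.logistic_transition(t, gt)), 20.0)
            clean = syn.simulate_esr_spectrum(model, n_points=1024)
            pairs.append(
                (
                    float(t),
                    syn.simulate_esr_spectrum(
                        model, n_points=1024,
                        noise_sd=np.max(np.abs(clean.intensity)) / snr,
                        seed=seed0 + i,
                    ),
                )
            )
        return pairs

    def test_order_decreases_with_temperature(self):
        pairs = self.spectra_series(temps=[292.0, 297.0, 305.0], snr=1e9)
        table = esr.order_temperature_profile(pairs)
        s = table.observable("S")
        assert s[0] > s[1] > s[2]

    def test_single_temperature_rejected(self):
        pairs = self.spectra_series(temps=[298.0])
        with pytest.raises(ValueError):
            esr.order_temperature_profile(pairs)

    def test_transition_midpoint_round_trip(self):
        table = esr.order_temperature_profile(self.spectra_series())
        fit = ph.fit_transition(table, column="S")
        assert fit.midpoint == pytest.approx(297.0, abs=0.5)
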