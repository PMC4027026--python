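import numpy as np
import pytest

from memspec import synthetic as syn


def snr_noise(clean_intensity, snr: float) -> float:
    """Noise standard deviation giving the requested peak signal-to-noise."""
    return float(np.max(np.abs(clean_intensity)) / snr)


@pytest.fixture
def dmpc_components():
    return syn.dmpc_d54_fixture("DMPC", 298.0)


@pytest.fixture
def single_doublet_spectrum():
    comp = [syn.PakeComponent(10.0, 1.0)]
    return syn.simulate_pake_spectrum(comp, broadening_khz=0.3, axis_range_khz=20.0,
                                      n_points=1024)


@pytest.fixture
def csa58_spectrum():
    model = syn.CsaModel(csa=58.0, broadening=1.0)
    return syn.simulate_csa_powder(model, n_points=2048)
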