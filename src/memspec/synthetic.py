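"""Synthetic spectra and series with known ground truth.

Every analysis stage in the package consumes either a :class:`Spectrum1D` or a
:class:`SeriesTable`; this module generates both for the four experiment
families — ²H Pake powder patterns, axially symmetric ³¹P CSA lineshapes,
first-derivative nitroxide ESR spectra, and the scalar series (temperature
scans, continuous-variations titrations).  All generators are deterministic
under a fixed seed, and all noise is additive Gaussian.

Powder patterns are computed by numerical orientation averaging: the director
orientation is sampled uniformly in cos θ (the isotropic powder measure) on a
grid of ≥ 2000 points, transition frequencies are binned onto the output axis,
and the stick pattern is convolved with a Lorentzian line.

The nitroxide derivative lineshape is a documented phenomenological
construction constrained only by the two measurable hyperfine separations
(outer derivative extrema at ±T∥ from the center, inner extrema at ±T⊥); it
is not a slow-motional simulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import RangeError
from .spectra import SeriesTable, Spectrum1D

__all__ = [
    "PakeComponent",
    "CsaModel",
    "EsrModel",
    "BindingGroundTruth",
    "TransitionGroundTruth",
    "simulate_pake_spectrum",
    "simulate_csa_powder",
    "simulate_esr_spectrum",
    "simulate_transition_series",
    "simulate_job_series",
    "dmpc_d54_fixture",
    "pake_lineshape",
]

DEFAULT_N_ORIENTATIONS = 2000


# ----------------------------------------------------------------------
# ground-truth containers
# ----------------------------------------------------------------------
@dataclass
class PakeComponent:
    """One C–D position: 90°-orientation quadrupolar splitting and deuteron count.

    ``splitting_90`` is the horn separation Δν_Q in kHz; the 0° shoulders of
    the powder doublet sit at twice that separation.
    """

    splitting_90: float
    weight: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.splitting_90 < 0:
            raise ValueError("splitting_90 must be >= 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class CsaModel:
    """Axially symmetric ³¹P shift tensor plus optional isotropic lines.

    ``csa`` is the lowfield-edge minus highfield-edge separation in ppm.
    ``isotropic_components`` is a list of (position_ppm, linewidth_hz, area)
    Lorentzians; the powder pattern itself is normalised to unit area, so each
    area is directly a fraction of the powder intensity.
    """

    csa: float
    iso_position: float = 0.0
    broadening: float = 1.0
    isotropic_components: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.csa < 0:
            raise ValueError("csa must be >= 0")
        if self.broadening <= 0:
            raise ValueError("broadening must be > 0")
        for pos, width, amp in self.isotropic_components:
            if width <= 0:
                raise ValueError("isotropic linewidths must be > 0")


@dataclass
class EsrModel:
    """Anisotropic nitroxide spectrum parameterised by its hyperfine extrema."""

    two_T_par: float
    two_T_perp: float
    center: float = 3480.0
    linewidth: float = 3.0

    def __post_init__(self) -> None:
        if not (self.two_T_par > self.two_T_perp > 0):
            raise ValueError("require two_T_par > two_T_perp > 0")
        if self.linewidth <= 0:
            raise ValueError("linewidth must be > 0")


@dataclass
class BindingGroundTruth:
    """1:1 fast-exchange binding truth for titration simulation.

    Shifts may be scalars (one resonance) or dicts keyed by resonance label.
    """

    log_ka: float
    delta_free: float | dict = 0.0
    delta_bound: float | dict = 0.1
    total_conc: float = 2e-3
    stoichiometry: tuple = (1, 1)

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_ka):
            raise ValueError("log_ka must be finite")
        if self.total_conc <= 0:
            raise ValueError("total_conc must be > 0")

    def shift_maps(self) -> tuple[dict, dict]:
        free = self.delta_free if isinstance(self.delta_free, dict) else {"H1": self.delta_free}
        bound = (
            self.delta_bound if isinstance(self.delta_bound, dict) else {"H1": self.delta_bound}
        )
        if set(free) != set(bound):
            raise ValueError("delta_free and delta_bound must cover the same resonances")
        return free, bound


@dataclass
class TransitionGroundTruth:
    """Sigmoidal observable-vs-temperature truth (gel -> liquid-crystal)."""

    low_T_value: float
    high_T_value: float
    midpoint: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")


# ----------------------------------------------------------------------
# lineshape primitives
# ----------------------------------------------------------------------
def _lorentzian_kernel(dx: float, fwhm: float, n_axis: int) -> np.ndarray:
    """Unit-area discrete Lorentzian kernel on the axis grid (odd length)."""
    gamma = fwhm / 2.0
    half = min(int(np.ceil(40.0 * gamma / dx)), (n_axis - 1) // 2)
    x = np.arange(-half, half + 1) * dx
    k = gamma / (np.pi * (x * x + gamma * gamma))
    return k / k.sum() * 1.0  # normalised in counts; dx handled by caller


def _bin_frequencies(axis: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    dx = axis[1] - axis[0]
    edges = np.concatenate([axis - dx / 2, [axis[-1] + dx / 2]])
    counts, _ = np.histogram(freqs, bins=edges)
    return counts.astype(float)


def pake_lineshape(
    axis: np.ndarray,
    splitting_90: float,
    broadening: float,
    n_orientations: int = DEFAULT_N_ORIENTATIONS,
) -> np.ndarray:
    """Unit-area broadened powder doublet for one 90°-splitting.

    For director angle θ with cos θ uniform on (0, 1) the two transition
    frequencies are ν±(θ) = ±Δν₉₀ (3cos²θ − 1)/2, putting the horns at
    ±Δν₉₀/2 (separation Δν₉₀) and the 0° shoulders at ±Δν₉₀.
    """
    axis = np.asarray(axis, dtype=float)
    dx = axis[1] - axis[0]
    u = (np.arange(n_orientations) + 0.5) / n_orientations
    nu = splitting_90 * (3.0 * u * u - 1.0) / 2.0
    counts = _bin_frequencies(axis, np.concatenate([nu, -nu]))
    dens = counts / (2.0 * n_orientations * dx)
    if broadening > 0:
        kern = _lorentzian_kernel(dx, broadening, axis.size)
        dens = np.convolve(dens, kern, mode="same")
    return dens


def simulate_pake_spectrum(
    components,
    broadening_khz: float = 0.5,
    axis_range_khz: float = 45.0,
    n_points: int = 2048,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Spectrum1D:
    """Superposition of weighted powder doublets on a symmetric kHz axis.

    ``axis_range_khz`` is the half-range: the axis spans ±axis_range_khz and
    must cover the 0° shoulders (at ± the largest splitting) with margin.
    Noiseless output is symmetric about 0; integrated intensity is
    proportional to the sum of component weights.
    """
    if broadening_khz < 0:
        raise ValueError("broadening_khz must be >= 0")
    components = list(components)
    if components:
        max_split = max(c.splitting_90 for c in components)
        if axis_range_khz < max_split + 3.0 * broadening_khz:
            raise RangeError(
                f"axis half-range {axis_range_khz} kHz does not cover the 0° shoulders "
                f"at ±{max_split} kHz (plus broadening margin)"
            )
    axis = np.linspace(-axis_range_khz, axis_range_khz, n_points)
    intensity = np.zeros(n_points)
    for comp in components:
        intensity += comp.weight * pake_lineshape(axis, comp.splitting_90, broadening_khz)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, n_points)
    return Spectrum1D(
        axis,
        intensity,
        unit="kHz",
        mode="2H",
        metadata={"generator": "pake", "seed": seed, "broadening_khz": broadening_khz},
    )


def add_lorentzian(
    s: Spectrum1D, position: float, fwhm: float, area: float = 1.0
) -> Spectrum1D:
    """Return a copy of ``s`` with a unit-area-scaled Lorentzian line added.

    Used to superimpose isotropic components (solubilised lipid, membrane
    fragments) on powder patterns; ``fwhm`` is in axis units.
    """
    gamma = fwhm / 2.0
    line = area * gamma / (np.pi * ((s.axis - position) ** 2 + gamma**2))
    return s.replace(intensity=s.intensity + line)


def simulate_csa_powder(
    model: CsaModel,
    n_points: int = 2048,
    noise_sd: float = 0.0,
    seed: int | None = None,
    axis_margin: float | None = None,
    reference_frequency: float = 162.0,
    n_orientations: int = DEFAULT_N_ORIENTATIONS,
) -> Spectrum1D:
    """Axially symmetric CSA powder lineshape (unit area) plus isotropic lines.

    The tensor is oriented so the perpendicular edge (the intensity maximum)
    sits lowfield of the parallel edge, as for lamellar-phase phospholipids:
    σ⊥ = iso + csa/3, σ∥ = iso − 2·csa/3, so the edge separation is exactly
    ``model.csa``.  Isotropic Lorentzians have their linewidths given in Hz
    and are converted to ppm with ``reference_frequency`` (MHz).
    """
    iso, csa = model.iso_position, model.csa
    if axis_margin is None:
        axis_margin = max(6.0 * model.broadening, 0.15 * csa, 2.0)
    lo = iso - max(csa, 1.0) - axis_margin
    hi = iso + max(csa, 1.0) + axis_margin
    axis = np.linspace(lo, hi, n_points)
    dx = axis[1] - axis[0]
    u = (np.arange(n_orientations) + 0.5) / n_orientations
    sigma_perp = iso + csa / 3.0
    sigma_par = iso - 2.0 * csa / 3.0
    nu = sigma_perp + (sigma_par - sigma_perp) * u * u
    dens = _bin_frequencies(axis, nu) / (n_orientations * dx)
    kern = _lorentzian_kernel(dx, model.broadening, n_points)
    dens = np.convolve(dens, kern, mode="same")
    for pos, width_hz, area in model.isotropic_components:
        width_ppm = width_hz / reference_frequency
        gamma = width_ppm / 2.0
        dens += area * gamma / (np.pi * ((axis - pos) ** 2 + gamma**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dens = dens + rng.normal(0.0, noise_sd, n_points)
    return Spectrum1D(
        axis,
        dens,
        unit="ppm",
        mode="31P",
        metadata={"generator": "csa_powder", "seed": seed,
                  "reference_frequency_MHz": reference_frequency},
    )


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def simulate_esr_spectrum(
    model: EsrModel,
    n_points: int = 2048,
    noise_sd: float = 0.0,
    seed: int | None = None,
    axis_margin: float = 15.0,
) -> Spectrum1D:
    """Phenomenological first-derivative nitroxide spectrum.

    The curve is a sum of Gaussian features placed so that the outermost
    derivative maximum/minimum sit at center ∓ T∥ (separation 2T∥) and the
    flanking inner maximum/minimum at center ∓ T⊥ (separation 2T⊥), with a
    central derivative-shaped m = 0 feature.  Amplitudes follow the usual
    appearance of 5-doxyl spectra (inner features taller than outer wings).
    """
    t_par = model.two_T_par / 2.0
    t_perp = model.two_T_perp / 2.0
    c = model.center
    w = model.linewidth
    half_range = t_par + axis_margin
    axis = np.linspace(c - half_range, c + half_range, n_points)
    # feature widths capped so neighbouring features do not displace the
    # extrema away from their defining positions
    w_eff = min(w, 0.25 * (t_par - t_perp), 0.6 * t_perp)
    y = _gauss(axis, c - t_par, w_eff) - _gauss(axis, c + t_par, w_eff)
    y += 2.0 * (_gauss(axis, c - t_perp, w_eff) - _gauss(axis, c + t_perp, w_eff))
    # central m=0 derivative feature, kept narrow and inside the T_perp pair
    sig0 = min(w_eff, 0.3 * t_perp)
    y += 0.8 * (-(axis - c) / sig0) * _gauss(axis, c, sig0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, n_points)
    return Spectrum1D(
        axis,
        y,
        unit="Gauss",
        mode="ESR-derivative",
        metadata={"generator": "esr_derivative", "seed": seed},
    )


def simulate_isotropic_esr_triplet(
    splitting: float = 15.0,
    center: float = 3480.0,
    linewidth: float = 1.2,
    n_points: int = 2048,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Spectrum1D:
    """Three narrow symmetric derivative lines — a free (unincorporated) probe."""
    half_range = splitting + 12.0
    axis = np.linspace(center - half_range, center + half_range, n_points)
    y = np.zeros(n_points)
    for mu in (center - splitting, center, center + splitting):
        y += (-(axis - mu) / linewidth) * _gauss(axis, mu, linewidth)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, n_points)
    return Spectrum1D(axis, y, unit="Gauss", mode="ESR-derivative",
                      metadata={"generator": "esr_isotropic_triplet", "seed": seed})


# ----------------------------------------------------------------------
# series generators
# ----------------------------------------------------------------------
def logistic_transition(t, gt: TransitionGroundTruth):
    """Closed-form sigmoid: low value below the midpoint, high value above."""
    t = np.asarray(t, dtype=float)
    z = (gt.midpoint - t) / gt.width
    return gt.high_T_value + (gt.low_T_value - gt.high_T_value) / (1.0 + np.exp(-z))


def simulate_transition_series(
    gt: TransitionGroundTruth,
    temperatures,
    noise_sd: float = 0.0,
    seed: int | None = None,
    observable_name: str = "observable",
) -> SeriesTable:
    """Logistic observable(T) series with seeded additive noise."""
    temperatures = np.asarray(temperatures, dtype=float)
    if temperatures.size == 0:
        raise ValueError("temperature list must not be empty")
    y = logistic_transition(temperatures, gt)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, temperatures.size)
    return SeriesTable.from_columns("T_K", temperatures, **{observable_name: y})


def simulate_job_series(
    gt: BindingGroundTruth,
    fractions,
    noise_sd_ppm: float = 0.0,
    seed: int | None = None,
):
    """Continuous-variations titration at fixed total concentration.

    For host fraction F: H₀ = F·C_tot, G₀ = (1−F)·C_tot; the complex
    concentration comes from the exact 1:1 equilibrium and the observed host
    shift is the fast-exchange population average.  Returns a
    :class:`memspec.binding.TitrationSeries` carrying the true free shifts.
    """
    from .binding import TitrationSeries, observed_shift

    if gt.stoichiometry != (1, 1):
        raise ValueError("only 1:1 stoichiometry is supported")
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions <= 0) or np.any(fractions >= 1):
        raise ValueError("fractions must lie strictly inside (0, 1)")
    free, bound = gt.shift_maps()
    rng = np.random.default_rng(seed)
    shifts = {}
    for label in free:
        obs = np.array(
            [
                observed_shift(
                    f * gt.total_conc,
                    (1.0 - f) * gt.total_conc,
                    gt.log_ka,
                    free[label],
                    bound[label],
                )
                for f in fractions
            ]
        )
        if noise_sd_ppm > 0:
            obs = obs + rng.normal(0.0, noise_sd_ppm, fractions.size)
        shifts[label] = obs
    return TitrationSeries(
        fractions=fractions,
        shifts=shifts,
        total_conc=gt.total_conc,
        delta_free=dict(free),
    )


# free shifts of the six cyclodextrin-copolymer glucose protons (ppm, D2O)
# and the bound-shift changes used by the titration fixtures; the changes are
# package choices on the scale typical of cyclodextrin complexation
_POLYA_FREE = {"H1": 5.29, "H2": 3.85, "H3": 4.43, "H4": 4.27, "H5": 4.05, "H6": 4.30}
_POLYA_DELTA = {"H1": 0.06, "H2": 0.05, "H3": 0.15, "H4": 0.06, "H5": 0.12, "H6": 0.08}


def polya_titration_ground_truth(
    log_ka: float = 4.5, total_conc: float = 2e-3
) -> BindingGroundTruth:
    """Canonical six-resonance host/guest titration truth (2 mM total).

    Mirrors the continuous-variations experiment observed on the six glucose
    proton resonances of the cyclodextrin copolymer host.
    """
    bound = {k: _POLYA_FREE[k] + _POLYA_DELTA[k] for k in _POLYA_FREE}
    return BindingGroundTruth(
        log_ka=log_ka,
        delta_free=dict(_POLYA_FREE),
        delta_bound=bound,
        total_conc=total_conc,
    )


# ----------------------------------------------------------------------
# DMPC-d54 membrane fixtures
# ----------------------------------------------------------------------
# Endpoint splittings (kHz) at 298 K for the four systems: terminal methyl
# (CD3) and the C2–C8 plateau.  Intermediate C14…C9 methylenes carry no
# published per-position values and are linearly interpolated between the
# endpoints (configurable stand-in, not measured data).
_FIXTURE_ENDPOINTS_298 = {
    "DMPC": (4.0, 29.0),
    "DMPC+CYSP": (4.2, 31.0),
    "DMPC+POLYA": (3.6, 26.6),
    "DMPC+ASD": (4.4, 28.0),
}
# Above the main transition the chains fluidise; one global scale factor
# stands in for the (unpublished) 308 K per-position values.
_SCALE_308 = 0.85

_CD2_LABELS = ["C14", "C13", "C12", "C11", "C10", "C9"]


def dmpc_d54_fixture(system: str, temperature: float = 298.0):
    """Canonical 8-component acyl-chain splitting list for one membrane system.

    Weights count deuterons over both chains: CD3 = 6, each resolved CD2
    position = 4, plateau (C2–C8, 7 positions) = 28.
    """
    if system not in _FIXTURE_ENDPOINTS_298:
        raise ValueError(
            f"unknown system {system!r}; expected one of {sorted(_FIXTURE_ENDPOINTS_298)}"
        )
    if temperature not in (298, 298.0, 308, 308.0):
        raise ValueError("fixture temperatures are 298 K and 308 K")
    cd3, plateau = _FIXTURE_ENDPOINTS_298[system]
    scale = _SCALE_308 if float(temperature) == 308.0 else 1.0
    cd3, plateau = cd3 * scale, plateau * scale
    comps = [PakeComponent(cd3, 6.0, "CD3")]
    n_steps = len(_CD2_LABELS) + 1
    for i, label in enumerate(_CD2_LABELS, start=1):
        comps.append(PakeComponent(cd3 + (plateau - cd3) * i / (n_steps + 0.0), 4.0, label))
    comps.append(PakeComponent(plateau, 28.0, "plateau"))
    return comps
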