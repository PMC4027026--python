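"""Continuous-variations (Job) analysis and 1:1 association-constant fitting.

A host H and guest G in fast exchange form a 1:1 complex HG with association
constant Ka (M⁻¹).  The observed host chemical shift is the population
average δ_obs = δ_free + (δ_bound − δ_free)·[HG]/H₀, and [HG] follows from
the exact quadratic equilibrium solution.  The Job (continuous variations)
series holds the total concentration fixed while the host mole fraction F
varies; the host-weighted response |Δδ|·F peaks at the stoichiometric
fraction (0.5 for 1:1).  Ka is fitted on a log10 scale by multi-start
Nelder–Mead (simplex) least squares.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .errors import DegenerateInputError, NonIdentifiableError

__all__ = [
    "TitrationSeries",
    "JobCurve",
    "BindingFit",
    "binding_model",
    "observed_shift",
    "job_transform",
    "fit_association_constant",
    "AssociationConstantFitter",
]


def binding_model(H0: float, G0: float, log_ka: float) -> float:
    """Exact 1:1 complex concentration [HG] in M.

    With s = H₀ + G₀ + Kd (Kd = 10^(−log Ka)),
    [HG] = (s − sqrt(s² − 4 H₀G₀))/2, computed in the cancellation-free form
    2 H₀G₀ / (s + sqrt(s² − 4 H₀G₀)).  Bounded by min(H₀, G₀).
    """
    if H0 < 0 or G0 < 0:
        raise ValueError("concentrations must be >= 0")
    if H0 == 0 or G0 == 0:
        return 0.0
    kd = 10.0 ** (-log_ka)
    s = H0 + G0 + kd
    disc = s * s - 4.0 * H0 * G0
    hg = 2.0 * H0 * G0 / (s + np.sqrt(max(disc, 0.0)))
    return float(min(hg, H0, G0))


def observed_shift(
    H0: float, G0: float, log_ka: float, delta_free: float, delta_bound: float
) -> float:
    """Fast-exchange host shift: δ_free + (δ_bound − δ_free)·[HG]/H₀."""
    if H0 <= 0:
        raise ValueError("H0 must be > 0 for an observed host shift")
    hg = binding_model(H0, G0, log_ka)
    return float(delta_free + (delta_bound - delta_free) * hg / H0)


@dataclass
class TitrationSeries:
    """Observed per-resonance shifts versus host mole fraction.

    ``shifts`` maps resonance label -> ppm array (same length as
    ``fractions``); ``delta_free`` optionally maps label -> free-host shift
    (known from a pure-host spectrum, or carried by the generator).
    """

    fractions: np.ndarray
    shifts: dict
    total_conc: float
    delta_free: dict | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions <= 0) or np.any(self.fractions >= 1):
            raise ValueError("fractions must lie strictly inside (0, 1)")
        if self.total_conc <= 0:
            raise ValueError("total_conc must be > 0")
        for label, arr in list(self.shifts.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.fractions.shape:
                raise ValueError(f"shift column {label!r} length mismatch")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"shift column {label!r} contains non-finite values")
            self.shifts[label] = arr

    @property
    def labels(self) -> list:
        return list(self.shifts)


@dataclass
class JobCurve:
    """Weighted continuous-variations response per resonance."""

    fractions: np.ndarray
    response: dict
    argmax: dict
    pooled_argmax: float
    degenerate: bool = False


def _quadratic_argmax(x: np.ndarray, y: np.ndarray) -> float:
    """Position of the maximum, refined by a parabola through the top 3 points."""
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return float(x[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a >= 0:  # flat or concave-up triple: keep the grid point
        return float(x1)
    return float(-b / (2.0 * a))


def job_transform(
    series: TitrationSeries,
    delta_free: dict | None = None,
    weighting: str = "fraction",
) -> JobCurve:
    """Build the Job curve y(F) = |δ_obs − δ_free| · F per resonance.

    ``weighting='host'`` uses |Δδ|·H₀ instead; both peak at m/(m+n) for a
    noiseless 1:1 system.  Free shifts must be supplied here or carried by
    the series.  The pooled stoichiometric fraction is the median of the
    per-resonance (quadratically interpolated) maxima.
    """
    F = series.fractions
    if F.min() > 0.2 or F.max() < 0.8:
        raise ValueError("Job analysis needs fractions spanning at least (0.2, 0.8)")
    free = delta_free or series.delta_free
    if free is None:
        raise ValueError(
            "free-host shifts unknown: supply delta_free or a series with an F→1 anchor"
        )
    response: dict = {}
    argmax: dict = {}
    degenerate = True
    for label, obs in series.shifts.items():
        if label not in free:
            raise ValueError(f"no free shift supplied for resonance {label!r}")
        dd = np.abs(obs - free[label])
        y = dd * (F if weighting == "fraction" else F * series.total_conc)
        response[label] = y
        scale = max(np.max(np.abs(y)), 1e-300)
        if np.ptp(y) / scale < 1e-9:
            argmax[label] = np.nan
        else:
            degenerate = False
            argmax[label] = _quadratic_argmax(F, y)
    finite = [v for v in argmax.values() if np.isfinite(v)]
    pooled = float(np.median(finite)) if finite else np.nan
    if degenerate:
        warnings.warn("Job curve is flat: stoichiometric fraction undefined", stacklevel=2)
    return JobCurve(F, response, argmax, pooled, degenerate=degenerate)


@dataclass
class BindingFit:
    """Result of the simplex association-constant fit."""

    log_ka: float
    delta_bound: dict
    rss: float
    converged: bool
    n_iter: int
    delta_free: dict = field(default_factory=dict)


class AssociationConstantFitter(BaseEstimator):
    """Multi-start Nelder–Mead fit of log10 Ka and per-resonance bound shifts.

    Minimises the sum of squared shift residuals over all points and
    resonances of a 1:1 fast-exchange model.  Free shifts are held fixed
    (from the pure-host measurement); fitted parameters are log10 Ka and one
    δ_bound per resonance.  ``n_starts`` initial log10 Ka values are spaced
    over ``log_ka_bounds`` and the best-RSS simplex wins; the winner is
    polished by a second Nelder–Mead restart.

    Attributes (after ``fit``): ``log_ka_``, ``delta_bound_``, ``rss_``,
    ``converged_``, ``n_iter_``.
    """

    def __init__(
        self,
        n_starts: int = 5,
        log_ka_bounds: tuple = (1.0, 8.0),
        max_iter: int = 4000,
        tol: float = 1e-12,
    ):
        self.n_starts = n_starts
        self.log_ka_bounds = log_ka_bounds
        self.max_iter = max_iter
        self.tol = tol

    def _rss(self, params, F, C, obs_mat, free_vec):
        log_ka = params[0]
        if not (-2.0 <= log_ka <= 12.0):
            return 1e30
        bound = params[1:]
        rss = 0.0
        for k, f in enumerate(F):
            h0 = f * C
            g0 = (1.0 - f) * C
            frac = binding_model(h0, g0, log_ka) / h0
            model = free_vec + (bound - free_vec) * frac
            diff = model - obs_mat[:, k]
            rss += float(diff @ diff)
        return rss

    def fit(self, series: TitrationSeries, delta_free: dict | None = None):
        free = delta_free or series.delta_free
        if free is None:
            raise ValueError("fit requires known free-host shifts (delta_free)")
        if series.fractions.size < 5:
            raise ValueError("association-constant fit needs at least 5 points")
        labels = series.labels
        F = series.fractions
        C = series.total_conc
        obs_mat = np.vstack([series.shifts[lab] for lab in labels])
        free_vec = np.array([free[lab] for lab in labels])
        variation = float(np.max(np.ptp(obs_mat, axis=1)))
        span = max(float(np.max(np.abs(obs_mat - free_vec[:, None]))), 1e-12)
        if variation < 1e-6 * max(span, 1.0) or span < 1e-9:
            raise NonIdentifiableError(
                "titration shows no shift variation: Ka is not identifiable"
            )
        # bound-shift initial guess: extrapolate the largest deviation from free
        dev = obs_mat - free_vec[:, None]
        idx = np.argmax(np.abs(dev), axis=1)
        bound0 = free_vec + 1.2 * dev[np.arange(len(labels)), idx]
        lo, hi = self.log_ka_bounds
        starts = np.linspace(lo, hi, self.n_starts)
        best = None
        total_iter = 0
        for lk0 in starts:
            x0 = np.concatenate([[lk0], bound0])
            res = minimize(
                self._rss,
                x0,
                args=(F, C, obs_mat, free_vec),
                method="Nelder-Mead",
                options={
                    "maxiter": self.max_iter,
                    "xatol": self.tol,
                    "fatol": self.tol,
                },
            )
            total_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res
        # polish the winner with a fresh simplex
        res = minimize(
            self._rss,
            best.x,
            args=(F, C, obs_mat, free_vec),
            method="Nelder-Mead",
            options={"maxiter": self.max_iter, "xatol": self.tol, "fatol": self.tol},
        )
        total_iter += res.nit
        if res.fun <= best.fun:
            best = res
        self.log_ka_ = float(best.x[0])
        self.delta_bound_ = {lab: float(v) for lab, v in zip(labels, best.x[1:])}
        self.rss_ = float(best.fun)
        self.converged_ = bool(best.success)
        self.n_iter_ = int(total_iter)
        self.delta_free_ = {lab: float(v) for lab, v in zip(labels, free_vec)}
        return self

    def result_(self) -> BindingFit:
        return BindingFit(
            log_ka=self.log_ka_,
            delta_bound=self.delta_bound_,
            rss=self.rss_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            delta_free=self.delta_free_,
        )


def fit_association_constant(
    series: TitrationSeries,
    delta_free: dict | None = None,
    n_starts: int = 5,
    max_iter: int = 4000,
    tol: float = 1e-12,
) -> BindingFit:
    """Functional wrapper around :class:`AssociationConstantFitter`."""
    est = AssociationConstantFitter(n_starts=n_starts, max_iter=max_iter, tol=tol)
    est.fit(series, delta_free=delta_free)
    return est.result_()
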