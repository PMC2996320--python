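"""Quick-Weibull psychometric model for 2AFC discrimination vs. eccentricity.

The probability of a correct response at retinal eccentricity ``e`` (degrees
of visual angle) is

    p(e) = 0.5 + 0.5 * 2 ** (-(e / tau) ** beta)

a decreasing Quick (base-2) Weibull with chance floor 0.5 (two-alternative
forced choice) and ceiling 1.0 at the fovea. ``tau`` is the position
parameter — the eccentricity at which performance falls to 0.75 — and
``beta`` controls steepness. The model has a closed-form inverse and, for
any pair of curves in the family, the equal-performance mapping between
eccentricities is linear in log coordinates with slope beta1/beta2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "PsychometricCurve",
    "FitResult",
    "predict",
    "invert",
    "fit_psychometric",
    "fit_binomial_cells",
    "log_likelihood",
    "NonIdentifiableWarning",
    "TAU_BOUNDS",
    "BETA_BOUNDS",
]

CHANCE = 0.5
CEILING = 1.0

# Optimisation box for the maximum-likelihood fit (degrees; dimensionless).
TAU_BOUNDS = (1.0, 30.0)
BETA_BOUNDS = (0.5, 10.0)


class NonIdentifiableWarning(UserWarning):
    """Raised when calibration data cannot pin down the curve parameters."""


@dataclass(frozen=True)
class PsychometricCurve:
    """Quick-Weibull curve with position ``tau`` (deg) and steepness ``beta``."""

    tau: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.tau > 0 and np.isfinite(self.tau)):
            raise ValueError(f"tau must be positive and finite, got {self.tau}")
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise ValueError(f"beta must be positive and finite, got {self.beta}")

    def __call__(self, e):
        return predict(self, e)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of a :class:`PsychometricCurve`."""

    curve: PsychometricCurve
    log_likelihood: float
    converged: bool
    n_trials: int


def predict(curve: PsychometricCurve, e):
    """Probability correct at eccentricity ``e`` (degrees, scalar or array).

    Raises ``ValueError`` for negative eccentricities.
    """
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < 0):
        raise ValueError("eccentricity must be non-negative")
    p = CHANCE + (CEILING - CHANCE) * np.exp2(-((e_arr / curve.tau) ** curve.beta))
    if np.isscalar(e) or e_arr.ndim == 0:
        return float(p)
    return p


def invert(curve: PsychometricCurve, p):
    """Eccentricity at which the curve predicts probability correct ``p``.

    Closed form: e = tau * (-log2(2p - 1)) ** (1/beta). Only defined on the
    open performance range (0.5, 1).
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= CHANCE) | (p_arr >= CEILING)):
        raise ValueError("p must lie strictly between 0.5 and 1.0")
    e = curve.tau * (-np.log2(2.0 * p_arr - 1.0)) ** (1.0 / curve.beta)
    if np.isscalar(p) or p_arr.ndim == 0:
        return float(e)
    return e


def _aggregate(eccentricities, correct):
    """Collapse Bernoulli trials to binomial cells (e, n, k)."""
    e = np.asarray(eccentricities, dtype=float)
    c = np.asarray(correct, dtype=bool)
    if e.shape != c.shape:
        raise ValueError("eccentricities and correct must have the same length")
    uniq, inv = np.unique(e, return_inverse=True)
    n = np.bincount(inv, minlength=uniq.size).astype(float)
    k = np.bincount(inv, weights=c.astype(float), minlength=uniq.size)
    return uniq, n, k


def _nll(params, e, n, k):
    tau, beta = params
    p = CHANCE + (CEILING - CHANCE) * np.exp2(-((e / tau) ** beta))
    # clip for the k == n cells where p may round to 1.0 at e == 0
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def log_likelihood(curve: PsychometricCurve, eccentricities, correct) -> float:
    """Bernoulli log-likelihood of a curve on calibration outcomes (nats)."""
    e, n, k = _aggregate(eccentricities, correct)
    return -_nll((curve.tau, curve.beta), e, n, k)


# multi-start grid in log-parameter space; crossed pairs give 5+ starts
_TAU_STARTS = (2.0, 4.0, 7.0, 12.0, 20.0)
_BETA_STARTS = (1.0, 2.0, 4.0)


def fit_psychometric(
    eccentricities,
    correct,
    *,
    start: tuple[float, float] | None = None,
    multi_start: bool = True,
) -> FitResult:
    """Fit the Quick-Weibull curve to 2AFC calibration outcomes by ML.

    Parameters
    ----------
    eccentricities, correct
        Per-trial eccentricity (degrees) and correctness (bool).
    start
        Optional warm start ``(tau, beta)``; used alone when
        ``multi_start=False`` (bootstrap refits), otherwise added to the
        start grid.
    multi_start
        Run the bounded quasi-Newton optimiser from a grid of start points
        and keep the best (highest likelihood, then smallest tau).
    """
    e, n, k = _aggregate(eccentricities, correct)
    return fit_binomial_cells(e, n, k, start=start, multi_start=multi_start)


def fit_binomial_cells(
    e,
    n,
    k,
    *,
    start: tuple[float, float] | None = None,
    multi_start: bool = True,
) -> FitResult:
    """Fit from pre-aggregated cells: eccentricity, trials, correct counts.

    Same estimator as :func:`fit_psychometric`; the cell form is the natural
    unit for bootstrap refits, where each resample only perturbs the per-cell
    correct counts.
    """
    e = np.asarray(e, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    n_trials = int(n.sum())
    if e.size < 2:
        raise ValueError("need at least 2 distinct eccentricities to fit")

    total_k = k.sum()
    if total_k == 0 or total_k == n.sum():
        warnings.warn(
            "all responses correct or all incorrect: curve not identifiable; "
            "tau pinned to bound",
            NonIdentifiableWarning,
        )
        tau = TAU_BOUNDS[1] if total_k == n.sum() else TAU_BOUNDS[0]
        curve = PsychometricCurve(tau=tau, beta=BETA_BOUNDS[0])
        return FitResult(
            curve=curve,
            log_likelihood=-_nll((curve.tau, curve.beta), e, n, k),
            converged=False,
            n_trials=n_trials,
        )

    starts: list[tuple[float, float]] = []
    if start is not None:
        t0 = float(np.clip(start[0], *TAU_BOUNDS))
        b0 = float(np.clip(start[1], *BETA_BOUNDS))
        starts.append((t0, b0))
    if multi_start or not starts:
        starts.extend((t, b) for t in _TAU_STARTS for b in _BETA_STARTS)

    best = None
    for s in starts:
        res = minimize(
            _nll,
            x0=np.asarray(s),
            args=(e, n, k),
            method="L-BFGS-B",
            bounds=[TAU_BOUNDS, BETA_BOUNDS],
            options={"ftol": 1e-10, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-12 or (
            abs(res.fun - best.fun) <= 1e-12 and res.x[0] < best.x[0]
        ):
            best = res

    tau_hat, beta_hat = float(best.x[0]), float(best.x[1])
    eps = 1e-6
    at_bound = (
        tau_hat <= TAU_BOUNDS[0] + eps
        or tau_hat >= TAU_BOUNDS[1] - eps
        or beta_hat <= BETA_BOUNDS[0] + eps
        or beta_hat >= BETA_BOUNDS[1] - eps
    )
    if at_bound:
        warnings.warn(
            f"fit pinned to parameter bound (tau={tau_hat:.3g}, beta={beta_hat:.3g})",
            NonIdentifiableWarning,
        )
    return FitResult(
        curve=PsychometricCurve(tau=tau_hat, beta=beta_hat),
        log_likelihood=-float(best.fun),
        converged=bool(best.success) and not at_bound,
        n_trials=n_trials,
    )
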