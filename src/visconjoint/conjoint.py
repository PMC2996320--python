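"""Conjoint-measurement test battery: equivalence, transitivity, dominance.

The decision task asks whether an observer's choices between
eccentricity-contrast pairs are consistent with (equivalence), internally
coherent about (transitivity), and at least monotone in (dominance) their
own measured visual sensitivity. This module computes the three tests from
staircase records, completed dominance trials and calibration data, plus
the expected-gain accounting that prices the observed failures in reward
units.

Under the Quick-Weibull family the mapping between equally discriminable
eccentricities at two contrasts is log-linear,

    ln e2 = intercept + slope * ln e1,   slope = beta1 / beta2,

so transitivity is equivalent to the three directed transforms
(low->med, med->high, high->low) composing to the identity. The composite
intercept ``a`` and composite-slope deviation ``b`` (composite slope minus
one) are both zero for any self-consistent observer; their bootstrap
confidence intervals give the transitivity test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .observer import (
    CONTRAST_CYCLE,
    ECC_MAX,
    ECC_MIN,
    CalibrationTrial,
    ContrastLevel,
    DecisionTrial,
    EccContrastPair,
)
from .psychometric import (
    NonIdentifiableWarning,
    PsychometricCurve,
    fit_binomial_cells,
    invert,
    predict,
)
from .staircase import (
    DISCARD_REVERSALS,
    MIN_REVERSALS,
    EquivalencePoint,
    StaircaseRecord,
    estimate_pse,
)

__all__ = [
    "EquivalenceTransform",
    "TransitivityStatistics",
    "EquivalencePairStat",
    "EquivalenceTestResult",
    "DominanceResult",
    "GainReport",
    "analytic_transform",
    "fit_equivalence_transform",
    "transitivity_statistics",
    "transitivity_test",
    "equivalence_test",
    "dominance_test",
    "expected_gain_loss",
    "bootstrap_pses",
]

DEFAULT_BOOTSTRAP = 10_000


# --------------------------------------------------------------------------
# equivalence transforms and transitivity statistics

@dataclass(frozen=True)
class EquivalenceTransform:
    """Log-linear map between equally discriminable eccentricities.

    ``ln(e_to) = intercept + slope * ln(e_from)`` with natural logarithms.
    """

    from_contrast: ContrastLevel
    to_contrast: ContrastLevel
    intercept: float
    slope: float

    def apply(self, e: float) -> float:
        return math.exp(self.intercept + self.slope * math.log(e))


@dataclass(frozen=True)
class TransitivityStatistics:
    """Composite intercept/slope deviations with bootstrap intervals.

    ``a`` is the intercept of the composed cycle transform and ``b`` its
    slope minus one; both are exactly zero when the three directed
    equivalence transforms compose to the identity. Confidence intervals
    are percentile bootstrap at overall 95%, Bonferroni-corrected for the
    two statistics.
    """

    a: float
    b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    intransitive: bool
    n_boot: int


def analytic_transform(
    from_contrast: ContrastLevel,
    to_contrast: ContrastLevel,
    curve_from: PsychometricCurve,
    curve_to: PsychometricCurve,
) -> EquivalenceTransform:
    """Exact equivalence transform between two Quick-Weibull curves.

    Solving p_from(e1) = p_to(e2) gives slope beta1/beta2 and intercept
    ln(tau2) - slope * ln(tau1); the noiseless oracle for the fitted
    transforms.
    """
    slope = curve_from.beta / curve_to.beta
    intercept = math.log(curve_to.tau) - slope * math.log(curve_from.tau)
    return EquivalenceTransform(from_contrast, to_contrast, intercept, slope)


def _ols_loglog(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares of y on x, vectorised over rows of y; returns (a, b)."""
    xbar = x.mean()
    dx = x - xbar
    denom = float(np.sum(dx * dx))
    slope = (y - y.mean(axis=-1, keepdims=True)) @ dx / denom
    intercept = y.mean(axis=-1) - slope * xbar
    return intercept, slope


def fit_equivalence_transform(
    points: list[EquivalencePoint],
) -> EquivalenceTransform:
    """OLS fit of log(PSE) on log(fixed eccentricity) for one mapping.

    The experiment provides four points per directed mapping (anchor levels
    0.6-0.9); any number >= 2 with distinct fixed eccentricities works.
    """
    mappings = {p.mapping for p in points}
    if len(mappings) != 1:
        raise ValueError(f"points span multiple mappings: {mappings}")
    x = np.log([p.fixed.eccentricity for p in points])
    y = np.log([p.variable.eccentricity for p in points])
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct fixed eccentricities to fit")
    intercept, slope = _ols_loglog(x, y[None, :])
    (src, dst) = mappings.pop()
    return EquivalenceTransform(src, dst, float(intercept[0]), float(slope[0]))


def transitivity_statistics(
    t_lm: EquivalenceTransform,
    t_mh: EquivalenceTransform,
    t_hl: EquivalenceTransform,
) -> tuple[float, float]:
    """Composite (a, b) of the cycle low->med->high->low.

    Composing in log coordinates: slope B = b_LM * b_MH * b_HL and intercept
    A = a_HL + b_HL * (a_MH + b_MH * a_LM); returns (A, B - 1), both zero
    iff the composite is the identity.
    """
    expected = CONTRAST_CYCLE
    got = (
        (t_lm.from_contrast, t_lm.to_contrast),
        (t_mh.from_contrast, t_mh.to_contrast),
        (t_hl.from_contrast, t_hl.to_contrast),
    )
    if got != expected:
        raise ValueError(f"transforms do not form the contrast cycle: {got}")
    big_b = t_lm.slope * t_mh.slope * t_hl.slope
    big_a = t_hl.intercept + t_hl.slope * (t_mh.intercept + t_mh.slope * t_lm.intercept)
    return float(big_a), float(big_b - 1.0)


# --------------------------------------------------------------------------
# staircase replay bootstrap

def bootstrap_pses(
    record: StaircaseRecord, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap PSEs for one staircase by replaying its choice data.

    For each visited eccentricity the observed choices form an empirical
    pool; a replay re-runs the one-up one-down dynamics from the same start,
    drawing each trial's choice from the pool at the nearest visited
    eccentricity, and re-estimates the PSE (reversal mean, with the
    tail-mean fallback when a replay yields fewer than four reversals).
    Returns ``n_boot`` PSE values.
    """
    traj = record.trajectory
    chose_var = np.array([c == "VARIABLE" for c in record.choices])
    uniq = np.unique(traj)
    pools = [chose_var[np.isclose(traj, u)] for u in uniq]
    step = record.spec.step
    n = traj.size

    e = np.full(n_boot, traj[0])
    path = np.empty((n_boot, n))
    chosen = np.empty((n_boot, n), dtype=bool)
    for t in range(n):
        path[:, t] = e
        # nearest visited eccentricity
        pos = np.searchsorted(uniq, e)
        lo = np.clip(pos - 1, 0, uniq.size - 1)
        hi = np.clip(pos, 0, uniq.size - 1)
        idx = np.where(np.abs(uniq[lo] - e) <= np.abs(uniq[hi] - e), lo, hi)
        c = np.empty(n_boot, dtype=bool)
        for i in np.unique(idx):
            mask = idx == i
            pool = pools[i]
            c[mask] = pool[rng.integers(0, pool.size, size=int(mask.sum()))]
        chosen[:, t] = c
        e = np.clip(e + np.where(c, step, -step), ECC_MIN, ECC_MAX)

    flips = chosen[:, 1:] != chosen[:, :-1]
    pses = np.empty(n_boot)
    for b in range(n_boot):
        rev = np.nonzero(flips[b])[0] + 1
        if rev.size >= MIN_REVERSALS:
            pses[b] = path[b, rev[DISCARD_REVERSALS:]].mean()
        else:
            pses[b] = path[b, n // 2:].mean()
    return np.clip(pses, ECC_MIN, ECC_MAX)


def _grouped_records(
    records: list[StaircaseRecord],
) -> dict[tuple[ContrastLevel, ContrastLevel], list[StaircaseRecord]]:
    groups: dict = {m: [] for m in CONTRAST_CYCLE}
    for r in records:
        if r.spec.mapping not in groups:
            raise ValueError(f"unexpected mapping {r.spec.mapping}")
        groups[r.spec.mapping].append(r)
    return groups


# --------------------------------------------------------------------------
# transitivity test

def transitivity_test(
    records: list[StaircaseRecord],
    n_boot: int = DEFAULT_BOOTSTRAP,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    pse_method: str = "reversals",
) -> TransitivityStatistics:
    """Bootstrap test of transitivity from the full 12-staircase set.

    Point estimates come from the observed PSEs; ``n_boot`` replays of each
    staircase give percentile intervals for (a, b) at overall level
    ``alpha``, Bonferroni-corrected for the two statistics. The observer is
    flagged intransitive if either interval excludes zero.
    """
    rng = np.random.default_rng() if rng is None else rng
    groups = _grouped_records(records)

    transforms = {}
    for mapping, recs in groups.items():
        points = [estimate_pse(r, method=pse_method) for r in recs]
        transforms[mapping] = fit_equivalence_transform(points)
    a_hat, b_hat = transitivity_statistics(
        transforms[CONTRAST_CYCLE[0]],
        transforms[CONTRAST_CYCLE[1]],
        transforms[CONTRAST_CYCLE[2]],
    )

    comp_slope = np.ones(n_boot)
    comp_int = np.zeros(n_boot)
    # compose LM, then MH, then HL: A <- a_m + b_m * A, B <- b_m * B
    for mapping in CONTRAST_CYCLE:
        recs = groups[mapping]
        x = np.log([r.spec.fixed.eccentricity for r in recs])
        y = np.log(
            np.column_stack([bootstrap_pses(r, n_boot, rng) for r in recs])
        )
        intercept, slope = _ols_loglog(x, y)
        comp_int = intercept + slope * comp_int
        comp_slope = slope * comp_slope

    a_boot = comp_int
    b_boot = comp_slope - 1.0
    tail = alpha / 2.0 / 2.0  # two-sided, Bonferroni for two statistics
    ci_a = (
        float(np.quantile(a_boot, tail)),
        float(np.quantile(a_boot, 1.0 - tail)),
    )
    ci_b = (
        float(np.quantile(b_boot, tail)),
        float(np.quantile(b_boot, 1.0 - tail)),
    )
    intransitive = not (ci_a[0] <= 0.0 <= ci_a[1]) or not (ci_b[0] <= 0.0 <= ci_b[1])
    return TransitivityStatistics(
        a=a_hat, b=b_hat, ci_a=ci_a, ci_b=ci_b,
        intransitive=intransitive, n_boot=n_boot,
    )


# --------------------------------------------------------------------------
# equivalence test

@dataclass(frozen=True)
class EquivalencePairStat:
    """One subjective-indifference pair scored against true performance."""

    point: EquivalencePoint
    dp: float  # true p(lower-contrast member) - true p(higher-contrast member)
    ci: tuple[float, float]
    significant: bool
    ecc_error: float  # PSE minus the truly equivalent eccentricity (deg)


@dataclass(frozen=True)
class EquivalenceTestResult:
    """Equivalence test over the 12 subjective-indifference pairs."""

    pairs: list[EquivalencePairStat]
    mean_signed_dp: float
    t_p_value: float
    median_abs_ecc_error: float
    n_boot: int


def _calibration_cells(
    calibration: list[CalibrationTrial],
) -> dict[ContrastLevel, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Aggregate completed calibration trials to per-contrast binomial cells."""
    cells = {}
    for level in ContrastLevel:
        sub = [t for t in calibration if t.contrast == level]
        e = np.array([t.eccentricity for t in sub])
        c = np.array([t.correct for t in sub], dtype=float)
        uniq, inv = np.unique(e, return_inverse=True)
        n = np.bincount(inv, minlength=uniq.size).astype(float)
        k = np.bincount(inv, weights=c, minlength=uniq.size)
        cells[level] = (uniq, n, k)
    return cells


def _signed_dp(
    point: EquivalencePoint, fits: dict[ContrastLevel, PsychometricCurve]
) -> float:
    """True-probability difference, lower-contrast member minus higher."""
    pf = predict(fits[point.fixed.contrast], point.fixed.eccentricity)
    pv = predict(fits[point.variable.contrast], point.variable.eccentricity)
    if point.fixed.contrast < point.variable.contrast:
        return pf - pv
    return pv - pf


def equivalence_test(
    points: list[EquivalencePoint],
    records: list[StaircaseRecord],
    calibration: list[CalibrationTrial],
    fits: dict[ContrastLevel, PsychometricCurve],
    n_boot: int = DEFAULT_BOOTSTRAP,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    refit_calibration: bool = True,
) -> EquivalenceTestResult:
    """Score the 12 subjective-indifference pairs against true sensitivity.

    For each pair, the signed probability difference (lower-contrast member
    minus higher-contrast member, evaluated on the fitted true curves) is
    bootstrapped by resampling calibration trials within contrast x
    eccentricity cells (with curve refits, unless ``refit_calibration`` is
    off) jointly with staircase-replay PSEs; per-pair intervals carry a
    Bonferroni correction for the 12 tests at overall level ``alpha``. The
    mean signed difference across pairs is tested against zero with a
    two-tailed one-sample t-test, and eccentricity errors are reported
    relative to the truly equivalent eccentricity for each pair's anchor.
    """
    if len(points) != len(records):
        raise ValueError("points and records must align one-to-one")
    rng = np.random.default_rng() if rng is None else rng
    if n_boot < 100:
        import warnings

        warnings.warn("n_boot < 100: bootstrap intervals will be unstable")

    cells = _calibration_cells(calibration)

    # bootstrap PSEs per staircase, then bootstrap refits of the true curves
    pse_boot = [bootstrap_pses(r, n_boot, rng) for r in records]
    if refit_calibration:
        import warnings

        curve_boot: dict[ContrastLevel, list[PsychometricCurve]] = {}
        with warnings.catch_warnings():
            # resamples pinned at a parameter bound are routine; the warning
            # is meant for primary fits
            warnings.simplefilter("ignore", NonIdentifiableWarning)
            for level in ContrastLevel:
                e, n, k = cells[level]
                kstar = rng.binomial(n.astype(int), k / n, size=(n_boot, n.size))
                start = (fits[level].tau, fits[level].beta)
                curve_boot[level] = [
                    fit_binomial_cells(
                        e, n, kstar[b], start=start, multi_start=False
                    ).curve
                    for b in range(n_boot)
                ]
    else:
        curve_boot = {level: [fits[level]] * n_boot for level in ContrastLevel}

    tail = alpha / 12.0 / 2.0
    pair_stats: list[EquivalencePairStat] = []
    dps = []
    for point, pses in zip(points, pse_boot):
        dp = _signed_dp(point, fits)
        cf, cv = point.fixed.contrast, point.variable.contrast
        dps_b = np.empty(n_boot)
        for b in range(n_boot):
            pf = predict(curve_boot[cf][b], point.fixed.eccentricity)
            pv = predict(curve_boot[cv][b], float(pses[b]))
            dps_b[b] = (pf - pv) if cf < cv else (pv - pf)
        ci = (float(np.quantile(dps_b, tail)), float(np.quantile(dps_b, 1.0 - tail)))
        significant = not (ci[0] <= 0.0 <= ci[1])

        p_fixed = predict(fits[cf], point.fixed.eccentricity)
        p_fixed = min(max(p_fixed, 0.5 + 1e-9), 1.0 - 1e-12)
        correct_ecc = invert(fits[cv], p_fixed)
        ecc_error = point.variable.eccentricity - correct_ecc

        dps.append(dp)
        pair_stats.append(
            EquivalencePairStat(
                point=point, dp=dp, ci=ci, significant=significant,
                ecc_error=float(ecc_error),
            )
        )

    dps_arr = np.asarray(dps)
    if np.allclose(dps_arr, dps_arr[0]):
        # degenerate (e.g. noiseless observer): t-test undefined, no evidence
        t_p = 1.0 if abs(dps_arr.mean()) < 1e-12 else 0.0
    else:
        t_p = float(stats.ttest_1samp(dps_arr, 0.0).pvalue)
    return EquivalenceTestResult(
        pairs=pair_stats,
        mean_signed_dp=float(dps_arr.mean()),
        t_p_value=t_p,
        median_abs_ecc_error=float(
            np.median([abs(p.ecc_error) for p in pair_stats])
        ),
        n_boot=n_boot,
    )


# --------------------------------------------------------------------------
# dominance test

@dataclass(frozen=True)
class DominanceResult:
    """Dominance error rate for one condition with a 95% beta interval."""

    condition: str  # EQUI_CONTRAST | EQUI_ECCENTRICITY
    n: int
    errors: int
    rate: float
    ci: tuple[float, float]


def _beta_interval(errors: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed interval of Beta(errors + 1, n - errors + 1)."""
    tail = (1.0 - level) / 2.0
    lo, hi = stats.beta.ppf([tail, 1.0 - tail], errors + 1, n - errors + 1)
    return float(lo), float(hi)


def _is_dominance_error(trial: DecisionTrial) -> bool:
    a, b = trial.pair_fixed, trial.pair_variable
    if trial.origin == "EQUI_CONTRAST":
        if a.contrast != b.contrast or a.eccentricity == b.eccentricity:
            raise ValueError("equi-contrast trial must differ in eccentricity only")
        worse = "FIXED" if a.eccentricity > b.eccentricity else "VARIABLE"
    elif trial.origin == "EQUI_ECCENTRICITY":
        if a.eccentricity != b.eccentricity or a.contrast == b.contrast:
            raise ValueError("equi-eccentricity trial must differ in contrast only")
        worse = "FIXED" if a.contrast < b.contrast else "VARIABLE"
    else:
        raise ValueError(f"not a dominance trial: origin={trial.origin}")
    return trial.choice == worse


def dominance_test(trials: list[DecisionTrial]) -> dict[str, DominanceResult]:
    """Error rates for the equi-contrast and equi-eccentricity conditions.

    An error is choosing the larger eccentricity at equal contrast, or the
    lower contrast at equal eccentricity. The error proportion is treated as
    beta-distributed given the observed error and non-error counts, giving a
    95% equal-tailed interval.
    """
    out = {}
    for condition in ("EQUI_CONTRAST", "EQUI_ECCENTRICITY"):
        sub = [t for t in trials if t.origin == condition]
        if not sub:
            raise ValueError(f"no trials for condition {condition}")
        errors = sum(_is_dominance_error(t) for t in sub)
        n = len(sub)
        out[condition] = DominanceResult(
            condition=condition,
            n=n,
            errors=errors,
            rate=errors / n,
            ci=_beta_interval(errors, n),
        )
    return out


# --------------------------------------------------------------------------
# expected-gain accounting

@dataclass(frozen=True)
class GainReport:
    """Reward-weighted cost of suboptimal choices across decision trials."""

    reward_per_correct: float
    ideal_expected_gain: float
    actual_expected_gain: float
    loss_fraction: float


def expected_gain_loss(
    trials: list[DecisionTrial],
    fits: dict[ContrastLevel, PsychometricCurve],
    reward: float = 5.0,
) -> GainReport:
    """Expected-gain shortfall from not always choosing the better target.

    Per trial the loss is ``(max(p_A, p_B) - p_chosen) * reward`` with
    probabilities from the fitted true sensitivity curves; the loss fraction
    normalises total loss by the ideal expected gain.
    """
    ideal = 0.0
    actual = 0.0
    for t in trials:
        if t.choice not in ("FIXED", "VARIABLE"):
            raise ValueError("every trial needs a completed choice")
        p_f = predict(fits[t.pair_fixed.contrast], t.pair_fixed.eccentricity)
        p_v = predict(fits[t.pair_variable.contrast], t.pair_variable.eccentricity)
        p_chosen = p_f if t.choice == "FIXED" else p_v
        ideal += max(p_f, p_v) * reward
        actual += p_chosen * reward
    loss_fraction = 0.0 if ideal == 0 else (ideal - actual) / ideal
    return GainReport(
        reward_per_correct=reward,
        ideal_expected_gain=ideal,
        actual_expected_gain=actual,
        loss_fraction=float(loss_fraction),
    )
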