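"""Synthetic observers and the trial designs of the two-task experiment.

An observer carries two sets of Quick-Weibull sensitivity curves, one per
contrast level: the *true* map, which generates 2AFC calibration responses,
and a *subjective* map, which drives choices between eccentricity-contrast
pairs in the decision task. Distorting the subjective map (or supplying
per-mapping cross-contrast transforms, or switching to a lexicographic
semiorder rule) produces the patterned equivalence, transitivity and
dominance failures the analysis battery is designed to detect.

Stimulus geometry: targets appear at 18 eccentricities evenly spaced from
2 deg to 12.2 deg along the horizontal meridian, at one of three Weber
contrasts (low / medium / high).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .psychometric import PsychometricCurve, invert, predict

__all__ = [
    "ContrastLevel",
    "ChoiceRule",
    "EccContrastPair",
    "ObserverModel",
    "CalibrationTrial",
    "DecisionTrial",
    "ECC_MIN",
    "ECC_MAX",
    "N_LOCATIONS",
    "GRID_STEP",
    "eccentricity_grid",
    "CONTRAST_CYCLE",
    "make_observer",
    "veridical_observer",
    "contrast_misjudging_observer",
    "corkscrew_observer",
    "lexicographic_observer",
    "generate_calibration_design",
    "simulate_calibration",
    "simulate_choice",
    "choice_probability",
    "generate_dominance_design",
    "DesignError",
]

ECC_MIN = 2.0
ECC_MAX = 12.2
N_LOCATIONS = 18
GRID_STEP = (ECC_MAX - ECC_MIN) / (N_LOCATIONS - 1)  # 0.6 deg

CALIBRATION_BLOCKS = 5
CALIBRATION_REPS_PER_BLOCK = 6  # per contrast x location, half top / half bottom
DOMINANCE_REPS = 10
DOMINANCE_LEVEL = 0.75


class DesignError(ValueError):
    """A generated design violates the experiment's protocol."""


class ContrastLevel(enum.IntEnum):
    """Dot-on-square Weber contrast level; ordering LOW < MED < HIGH."""

    LOW = 0
    MED = 1
    HIGH = 2

    @property
    def nominal_contrast(self) -> float:
        """Nominal Weber contrast of the dot relative to the square.

        Metadata only (derived from the display luminances 74.4 / 80.7 /
        91.4 cd/m^2 against the 67.1 cd/m^2 square); never enters any
        computation.
        """
        return {0: 0.109, 1: 0.203, 2: 0.362}[int(self)]


# Directed cycle used by the staircase mappings and the transitivity test.
CONTRAST_CYCLE = (
    (ContrastLevel.LOW, ContrastLevel.MED),
    (ContrastLevel.MED, ContrastLevel.HIGH),
    (ContrastLevel.HIGH, ContrastLevel.LOW),
)


class ChoiceRule(enum.Enum):
    SUBJECTIVE_PROB = "subjective_prob"
    LEXICOGRAPHIC = "lexicographic"


@dataclass(frozen=True)
class EccContrastPair:
    """A target: eccentricity in degrees plus a contrast level."""

    eccentricity: float
    contrast: ContrastLevel

    def __post_init__(self) -> None:
        if not (ECC_MIN - 1e-9 <= self.eccentricity <= ECC_MAX + 1e-9):
            raise ValueError(
                f"eccentricity {self.eccentricity} outside [{ECC_MIN}, {ECC_MAX}]"
            )


@dataclass
class CalibrationTrial:
    """One 2AFC calibration trial (dot at top or bottom of the square)."""

    block: int
    contrast: ContrastLevel
    eccentricity: float
    stimulus: str  # TOP | BOTTOM
    response: str | None = None
    correct: bool | None = None


@dataclass
class DecisionTrial:
    """One decision-phase comparison between two eccentricity-contrast pairs."""

    pair_fixed: EccContrastPair
    pair_variable: EccContrastPair
    origin: str  # STAIRCASE | EQUI_CONTRAST | EQUI_ECCENTRICITY
    choice: str | None = None  # FIXED | VARIABLE


@dataclass
class ObserverModel:
    """Paired true/subjective sensitivity maps plus a stochastic choice rule.

    ``noise`` is an inverse temperature: the probability of choosing option A
    over B under the SUBJECTIVE_PROB rule is
    ``logistic(noise * (p_A - p_B))`` in subjective probability correct.
    ``noise = inf`` gives a deterministic maximiser. ``mapping_transforms``
    optionally distorts cross-contrast comparisons with a per-directed-
    mapping log-linear eccentricity transform ``(intercept, slope)``
    (natural-log scale); this is the generative hook for intransitive
    (lexicographic-semiorder-like, "corkscrew") observers, since any single
    consistent subjective map composes to the identity around the contrast
    cycle.
    """

    true_map: dict[ContrastLevel, PsychometricCurve]
    subjective_map: dict[ContrastLevel, PsychometricCurve]
    rule: ChoiceRule = ChoiceRule.SUBJECTIVE_PROB
    noise: float = 30.0
    semiorder_threshold: float = 2.0
    seed: int = 0
    lapse: float = 0.0
    mapping_transforms: dict[
        tuple[ContrastLevel, ContrastLevel], tuple[float, float]
    ] | None = None
    rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be in [0, 1]")
        _check_dominance(self.true_map)
        self.rng = np.random.default_rng(self.seed)

    def reseeded(self, seed: int) -> "ObserverModel":
        """Copy of this observer with a fresh seed (independent streams)."""
        return replace(self, seed=seed)


def eccentricity_grid() -> np.ndarray:
    """The 18 stimulus locations, evenly spaced on [2, 12.2] degrees."""
    return np.linspace(ECC_MIN, ECC_MAX, N_LOCATIONS)


def _check_dominance(true_map: dict[ContrastLevel, PsychometricCurve]) -> None:
    """True map must improve with contrast and degrade with eccentricity."""
    levels = sorted(ContrastLevel)
    if set(true_map) != set(levels):
        raise ValueError("true_map must define all three contrast levels")
    grid = eccentricity_grid()
    for lo, hi in zip(levels[:-1], levels[1:]):
        p_lo = predict(true_map[lo], grid)
        p_hi = predict(true_map[hi], grid)
        bad = np.nonzero(p_hi <= p_lo)[0]
        if bad.size:
            raise ValueError(
                "true_map violates contrast dominance at eccentricity "
                f"{grid[bad[0]]:.3f} deg ({hi.name} not better than {lo.name})"
            )
    # eccentricity dominance holds for any valid Quick-Weibull curve, but a
    # config may be checked before curve construction elsewhere; keep the
    # explicit grid check for symmetry with the contrast check
    for level in levels:
        p = predict(true_map[level], grid)
        bad = np.nonzero(np.diff(p) >= 0)[0]
        if bad.size:
            raise ValueError(
                "true_map violates eccentricity dominance at eccentricity "
                f"{grid[bad[0] + 1]:.3f} deg ({level.name})"
            )


def _curve_map(params: dict) -> dict[ContrastLevel, PsychometricCurve]:
    return {
        level: PsychometricCurve(
            tau=float(params[level.name]["tau"]), beta=float(params[level.name]["beta"])
        )
        for level in ContrastLevel
    }


def make_observer(config: dict, seed: int | None = None) -> ObserverModel:
    """Build an :class:`ObserverModel` from a JSON-style config dict.

    Expected keys: ``true_map`` and ``subjective_map`` (each mapping
    "LOW"/"MED"/"HIGH" to ``{"tau": .., "beta": ..}``), optional ``rule``
    ("subjective_prob" | "lexicographic"), ``noise``, ``semiorder_threshold``,
    ``lapse``, ``mapping_transforms`` (mapping "LOW->MED" style keys to
    ``[intercept, slope]``) and ``seed``. A ``seed`` argument overrides the
    config's.
    """
    true_map = _curve_map(config["true_map"])
    subjective_map = _curve_map(config.get("subjective_map", config["true_map"]))
    transforms = None
    if config.get("mapping_transforms"):
        transforms = {}
        for key, (a, b) in config["mapping_transforms"].items():
            src, dst = key.split("->")
            transforms[(ContrastLevel[src], ContrastLevel[dst])] = (float(a), float(b))
    return ObserverModel(
        true_map=true_map,
        subjective_map=subjective_map,
        rule=ChoiceRule(config.get("rule", "subjective_prob")),
        noise=float(config.get("noise", 30.0)),
        semiorder_threshold=float(config.get("semiorder_threshold", 2.0)),
        lapse=float(config.get("lapse", 0.0)),
        mapping_transforms=transforms,
        seed=int(config["seed"] if seed is None else seed),
    )


# --------------------------------------------------------------------------
# observer presets

# Default study conditions: sensitivity near ceiling at 2 deg, chance beyond
# ~12 deg (LOW), with all staircase anchor points (p in 0.6..0.9 per contrast)
# and the p=0.75 dominance eccentricities inside the 2-12.2 deg range with
# enough margin that calibration-fit noise rarely pushes an anchor outside.
DEFAULT_TRUE_MAP = {
    ContrastLevel.LOW: PsychometricCurve(tau=4.8, beta=2.5),
    ContrastLevel.MED: PsychometricCurve(tau=6.0, beta=2.6),
    ContrastLevel.HIGH: PsychometricCurve(tau=7.0, beta=2.7),
}


def veridical_observer(
    seed: int = 0,
    noise: float = 30.0,
    true_map: dict[ContrastLevel, PsychometricCurve] | None = None,
) -> ObserverModel:
    """Observer whose subjective map equals the true map (null observer)."""
    tm = dict(true_map or DEFAULT_TRUE_MAP)
    return ObserverModel(true_map=tm, subjective_map=dict(tm), noise=noise, seed=seed)


def contrast_misjudging_observer(
    seed: int = 0,
    tau_scale: float = 0.8,
    noise: float = 30.0,
) -> ObserverModel:
    """Observer who misjudges the benefit of contrast.

    ``tau_scale < 1`` compresses the subjective tau spread around the medium
    contrast (contrast-effect underestimation: the subjective curves are too
    similar, so equivalence errors all share one sign); ``tau_scale > 1``
    exaggerates it.
    """
    tm = dict(DEFAULT_TRUE_MAP)
    tau_med = tm[ContrastLevel.MED].tau
    sm = {
        level: PsychometricCurve(
            tau=tau_med * (curve.tau / tau_med) ** tau_scale, beta=curve.beta
        )
        for level, curve in tm.items()
    }
    return ObserverModel(true_map=tm, subjective_map=sm, noise=noise, seed=seed)


def corkscrew_observer(
    seed: int = 0,
    composite_slope: float = 2.0,
    pivot: float = 5.0,
    noise: float = 30.0,
) -> ObserverModel:
    """Intransitive observer whose cross-contrast mappings spiral outward.

    Each directed mapping of the contrast cycle gets the veridical log-linear
    equivalence transform with its slope multiplied by
    ``composite_slope**(1/3)``, re-anchored at ``pivot`` degrees so the
    distortion exaggerates eccentricity differences without moving the centre
    of the operating range. The three slopes then compose to
    ``composite_slope`` instead of 1.
    """
    tm = dict(DEFAULT_TRUE_MAP)
    gamma = composite_slope ** (1.0 / 3.0)
    transforms = {}
    for src, dst in CONTRAST_CYCLE:
        c1, c2 = tm[src], tm[dst]
        slope = c1.beta / c2.beta
        intercept = math.log(c2.tau) - slope * math.log(c1.tau)
        new_slope = slope * gamma
        anchor = intercept + slope * math.log(pivot)  # log-ecc image of pivot
        new_intercept = anchor - new_slope * math.log(pivot)
        transforms[(src, dst)] = (new_intercept, new_slope)
    return ObserverModel(
        true_map=tm,
        subjective_map=dict(tm),
        noise=noise,
        seed=seed,
        mapping_transforms=transforms,
    )


def lexicographic_observer(
    seed: int = 0,
    threshold: float = 2.0,
    lapse: float = 0.02,
) -> ObserverModel:
    """Observer using a lexicographic semiorder: eccentricity first.

    If the eccentricity difference exceeds ``threshold`` degrees the nearer
    target wins; otherwise the higher contrast wins. ``lapse`` flips the
    choice with small probability.
    """
    tm = dict(DEFAULT_TRUE_MAP)
    return ObserverModel(
        true_map=tm,
        subjective_map=dict(tm),
        rule=ChoiceRule.LEXICOGRAPHIC,
        semiorder_threshold=threshold,
        lapse=lapse,
        seed=seed,
    )


# --------------------------------------------------------------------------
# calibration task

def generate_calibration_design(
    rng: np.random.Generator | None = None,
) -> list[CalibrationTrial]:
    """Calibration design: 3 contrasts x 18 eccentricities x 5 blocks x 6 reps.

    Within each block and cell, half the dots are at the top and half at the
    bottom; trials are shuffled within block when ``rng`` is given, kept in
    canonical order otherwise. Total 1620 trials.
    """
    grid = eccentricity_grid()
    trials: list[CalibrationTrial] = []
    for block in range(CALIBRATION_BLOCKS):
        block_trials: list[CalibrationTrial] = []
        for contrast in ContrastLevel:
            for ecc in grid:
                for rep in range(CALIBRATION_REPS_PER_BLOCK):
                    stim = "TOP" if rep < CALIBRATION_REPS_PER_BLOCK // 2 else "BOTTOM"
                    block_trials.append(
                        CalibrationTrial(
                            block=block,
                            contrast=contrast,
                            eccentricity=float(ecc),
                            stimulus=stim,
                        )
                    )
        if rng is not None:
            order = rng.permutation(len(block_trials))
            block_trials = [block_trials[i] for i in order]
        trials.extend(block_trials)
    return trials


def simulate_calibration(
    observer: ObserverModel, design: list[CalibrationTrial]
) -> list[CalibrationTrial]:
    """Fill in responses: correct with probability true_map[contrast](e)."""
    out: list[CalibrationTrial] = []
    for t in design:
        p = predict(observer.true_map[t.contrast], t.eccentricity)
        correct = bool(observer.rng.random() < p)
        response = t.stimulus if correct else ("BOTTOM" if t.stimulus == "TOP" else "TOP")
        out.append(
            CalibrationTrial(
                block=t.block,
                contrast=t.contrast,
                eccentricity=t.eccentricity,
                stimulus=t.stimulus,
                response=response,
                correct=correct,
            )
        )
    return out


# --------------------------------------------------------------------------
# decision task: choices

def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def choice_probability(
    observer: ObserverModel, a: EccContrastPair, b: EccContrastPair
) -> float:
    """Probability that the observer chooses ``a`` over ``b``.

    Exposed separately from :func:`simulate_choice` so oracles (grid search
    for the 50% preference point) and the deterministic limit can query the
    model without consuming random numbers.
    """
    if observer.rule is ChoiceRule.LEXICOGRAPHIC:
        de = a.eccentricity - b.eccentricity
        if abs(de) > observer.semiorder_threshold:
            base = 1.0 if de < 0 else 0.0
        elif a.contrast != b.contrast:
            base = 1.0 if a.contrast > b.contrast else 0.0
        elif de != 0.0:
            base = 1.0 if de < 0 else 0.0
        else:
            base = 0.5
        return base * (1.0 - observer.lapse) + (1.0 - base) * observer.lapse

    p_a, p_b = _subjective_probs(observer, a, b)
    if math.isinf(observer.noise):
        base = 0.5 if p_a == p_b else (1.0 if p_a > p_b else 0.0)
    else:
        base = _logistic(observer.noise * (p_a - p_b))
    return base * (1.0 - observer.lapse) + (1.0 - base) * observer.lapse


def _subjective_probs(
    observer: ObserverModel, a: EccContrastPair, b: EccContrastPair
) -> tuple[float, float]:
    """Subjective probabilities the observer assigns to the two targets."""
    tf = observer.mapping_transforms
    if tf is not None and a.contrast != b.contrast:
        key_ab = (a.contrast, b.contrast)
        key_ba = (b.contrast, a.contrast)
        if key_ab in tf:
            intercept, slope = tf[key_ab]
            e_a_mapped = math.exp(intercept + slope * math.log(a.eccentricity))
            curve = observer.subjective_map[b.contrast]
            return (
                predict(curve, e_a_mapped),
                predict(curve, b.eccentricity),
            )
        if key_ba in tf:
            intercept, slope = tf[key_ba]
            e_b_mapped = math.exp(intercept + slope * math.log(b.eccentricity))
            curve = observer.subjective_map[a.contrast]
            return (
                predict(curve, a.eccentricity),
                predict(curve, e_b_mapped),
            )
    return (
        predict(observer.subjective_map[a.contrast], a.eccentricity),
        predict(observer.subjective_map[b.contrast], b.eccentricity),
    )


def simulate_choice(
    observer: ObserverModel, a: EccContrastPair, b: EccContrastPair
) -> str:
    """Simulate one choice between targets; returns 'FIRST' or 'SECOND'."""
    p_first = choice_probability(observer, a, b)
    if p_first == 1.0:
        return "FIRST"
    if p_first == 0.0:
        return "SECOND"
    return "FIRST" if observer.rng.random() < p_first else "SECOND"


# --------------------------------------------------------------------------
# dominance design

def generate_dominance_design(
    fits: dict[ContrastLevel, PsychometricCurve],
) -> list[DecisionTrial]:
    """Dominance trials anchored at each fitted curve's p = 0.75 point.

    Equi-contrast: 3 contrasts x 3 eccentricity pairs x 10 reps = 90 trials.
    Equi-eccentricity: 3 eccentricities x 3 contrast pairs x 10 reps = 90.
    """
    e75 = {}
    for level in ContrastLevel:
        e = invert(fits[level], DOMINANCE_LEVEL)
        if not (ECC_MIN <= e <= ECC_MAX):
            raise DesignError(
                f"p=0.75 eccentricity for {level.name} is {e:.2f} deg, outside "
                f"[{ECC_MIN}, {ECC_MAX}]: curve too steep or too shallow for "
                "the protocol"
            )
        e75[level] = float(e)

    eccs = [e75[level] for level in ContrastLevel]
    ecc_pairs = [(eccs[0], eccs[1]), (eccs[0], eccs[2]), (eccs[1], eccs[2])]
    contrast_pairs = [
        (ContrastLevel.LOW, ContrastLevel.MED),
        (ContrastLevel.LOW, ContrastLevel.HIGH),
        (ContrastLevel.MED, ContrastLevel.HIGH),
    ]

    trials: list[DecisionTrial] = []
    for contrast in ContrastLevel:
        for e1, e2 in ecc_pairs:
            for _ in range(DOMINANCE_REPS):
                trials.append(
                    DecisionTrial(
                        pair_fixed=EccContrastPair(e1, contrast),
                        pair_variable=EccContrastPair(e2, contrast),
                        origin="EQUI_CONTRAST",
                    )
                )
    for ecc in eccs:
        for c1, c2 in contrast_pairs:
            for _ in range(DOMINANCE_REPS):
                trials.append(
                    DecisionTrial(
                        pair_fixed=EccContrastPair(ecc, c1),
                        pair_variable=EccContrastPair(ecc, c2),
                        origin="EQUI_ECCENTRICITY",
                    )
                )
    return trials
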