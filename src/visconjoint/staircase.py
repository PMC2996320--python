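"""One-up one-down adaptive staircases over target eccentricity.

Each staircase fixes one eccentricity-contrast pair (at the eccentricity
where its fitted calibration curve predicts probability correct 0.6, 0.7,
0.8 or 0.9) and varies the eccentricity of a target at another contrast.
Choosing the variable target pushes it outward by one step (harder);
rejecting it pulls it inward (easier). The procedure therefore hovers
around the eccentricity at which the observer is indifferent — the point
of subjective equality (PSE), estimated from the staircase's reversals.

Twelve staircases (3 directed contrast mappings x 4 anchor probabilities)
are randomly interleaved with 180 dominance trials in one trial stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .observer import (
    CONTRAST_CYCLE,
    ECC_MAX,
    ECC_MIN,
    GRID_STEP,
    ContrastLevel,
    DecisionTrial,
    DesignError,
    EccContrastPair,
    ObserverModel,
    choice_probability,
    simulate_choice,
)
from .psychometric import PsychometricCurve, invert

__all__ = [
    "StaircaseSpec",
    "StaircaseRecord",
    "EquivalencePoint",
    "StaircaseError",
    "ANCHOR_LEVELS",
    "N_STAIRCASE_TRIALS",
    "build_staircase_specs",
    "run_staircase",
    "run_decision_phase",
    "find_reversals",
    "estimate_pse",
]

ANCHOR_LEVELS = (0.6, 0.7, 0.8, 0.9)
N_STAIRCASE_TRIALS = 70
DEFAULT_STEP = GRID_STEP  # 0.6 deg, one grid spacing
MIN_REVERSALS = 4
DISCARD_REVERSALS = 2


class StaircaseError(RuntimeError):
    """A staircase failed to produce a usable equivalence estimate."""


@dataclass(frozen=True)
class StaircaseSpec:
    """One staircase: a fixed anchor target and a variable-contrast target."""

    fixed: EccContrastPair
    variable_contrast: ContrastLevel
    level: float  # anchor probability of the fixed target (design value)
    start_eccentricity: float | None = None  # default: the fixed eccentricity
    step: float = DEFAULT_STEP
    n_trials: int = N_STAIRCASE_TRIALS

    def __post_init__(self) -> None:
        if self.fixed.contrast == self.variable_contrast:
            raise ValueError("fixed and variable contrasts must differ")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def mapping(self) -> tuple[ContrastLevel, ContrastLevel]:
        return (self.fixed.contrast, self.variable_contrast)


@dataclass
class StaircaseRecord:
    """Trajectory of one staircase: presented eccentricities and choices."""

    spec: StaircaseSpec
    trajectory: np.ndarray  # variable eccentricity presented on each trial
    choices: list[str]  # FIXED | VARIABLE per trial
    reversals: list[int] = field(default_factory=list)  # trial indices

    def reversal_eccentricities(self) -> np.ndarray:
        return self.trajectory[self.reversals]


@dataclass(frozen=True)
class EquivalencePoint:
    """A pair of targets the observer treats as equally discriminable."""

    fixed: EccContrastPair
    variable: EccContrastPair  # eccentricity = estimated PSE
    mapping: tuple[ContrastLevel, ContrastLevel]
    level: float


def build_staircase_specs(
    fits: dict[ContrastLevel, PsychometricCurve],
    levels: tuple[float, ...] = ANCHOR_LEVELS,
    step: float = DEFAULT_STEP,
    n_trials: int = N_STAIRCASE_TRIALS,
) -> list[StaircaseSpec]:
    """The experiment's 12 staircases: 3 directed mappings x 4 anchor levels.

    Anchor eccentricities come from inverting each observer's own fitted
    calibration curves, as in the protocol.
    """
    specs = []
    for src, dst in CONTRAST_CYCLE:
        for level in levels:
            e_fixed = invert(fits[src], level)
            if not (ECC_MIN <= e_fixed <= ECC_MAX):
                raise DesignError(
                    f"anchor eccentricity {e_fixed:.2f} deg for {src.name} at "
                    f"p={level} lies outside [{ECC_MIN}, {ECC_MAX}]"
                )
            specs.append(
                StaircaseSpec(
                    fixed=EccContrastPair(float(e_fixed), src),
                    variable_contrast=dst,
                    level=level,
                    step=step,
                    n_trials=n_trials,
                )
            )
    return specs


class _StaircaseState:
    """Mutable state advanced one trial at a time by the scheduler."""

    def __init__(self, spec: StaircaseSpec):
        self.spec = spec
        start = spec.start_eccentricity
        if start is None:
            start = spec.fixed.eccentricity
        self.current = float(np.clip(start, ECC_MIN, ECC_MAX))
        self.trajectory: list[float] = []
        self.choices: list[str] = []

    def step(self, observer: ObserverModel) -> DecisionTrial:
        variable = EccContrastPair(self.current, self.spec.variable_contrast)
        raw = simulate_choice(observer, self.spec.fixed, variable)
        choice = "FIXED" if raw == "FIRST" else "VARIABLE"
        self.trajectory.append(self.current)
        self.choices.append(choice)
        # chosen variable -> made harder (outward); rejected -> easier (inward)
        delta = self.spec.step if choice == "VARIABLE" else -self.spec.step
        self.current = float(np.clip(self.current + delta, ECC_MIN, ECC_MAX))
        return DecisionTrial(
            pair_fixed=self.spec.fixed,
            pair_variable=variable,
            origin="STAIRCASE",
            choice=choice,
        )

    def record(self) -> StaircaseRecord:
        traj = np.asarray(self.trajectory)
        rec = StaircaseRecord(spec=self.spec, trajectory=traj, choices=list(self.choices))
        rec.reversals = find_reversals(rec.choices)
        return rec


def run_staircase(observer: ObserverModel, spec: StaircaseSpec) -> StaircaseRecord:
    """Run one staircase to completion (no interleaving)."""
    state = _StaircaseState(spec)
    for _ in range(spec.n_trials):
        state.step(observer)
    return state.record()


def run_decision_phase(
    observer: ObserverModel,
    specs: list[StaircaseSpec],
    dominance_stubs: list[DecisionTrial],
) -> tuple[list[StaircaseRecord], list[DecisionTrial], list[DecisionTrial]]:
    """Run the full decision phase: staircase + dominance trials interleaved.

    All trials are shuffled into one stream with the observer's random
    stream; each staircase's state advances only on its own trials, so the
    within-staircase trial order is preserved. Returns the staircase
    records, the completed dominance trials, and the full global trial log.
    """
    if len(specs) != 12:
        raise DesignError(f"expected 12 staircase specs, got {len(specs)}")
    states = [_StaircaseState(s) for s in specs]
    tokens = [("S", i) for i, s in enumerate(specs) for _ in range(s.n_trials)]
    tokens += [("D", j) for j in range(len(dominance_stubs))]
    order = observer.rng.permutation(len(tokens))

    log: list[DecisionTrial] = []
    dominance: list[DecisionTrial] = [None] * len(dominance_stubs)  # type: ignore
    for idx in order:
        kind, which = tokens[idx]
        if kind == "S":
            log.append(states[which].step(observer))
        else:
            stub = dominance_stubs[which]
            raw = simulate_choice(observer, stub.pair_fixed, stub.pair_variable)
            done = DecisionTrial(
                pair_fixed=stub.pair_fixed,
                pair_variable=stub.pair_variable,
                origin=stub.origin,
                choice="FIXED" if raw == "FIRST" else "VARIABLE",
            )
            dominance[which] = done
            log.append(done)
    return [s.record() for s in states], list(dominance), log


def find_reversals(choices: list[str]) -> list[int]:
    """Trial indices where the staircase movement direction flips.

    The direction on trial t is set by the choice on trial t (outward if
    VARIABLE, inward if FIXED); a reversal is a trial whose direction differs
    from the previous trial's. Boundary clipping never changes a choice, so
    clipped moves cannot create reversals.
    """
    idx = []
    for t in range(1, len(choices)):
        if choices[t] != choices[t - 1]:
            idx.append(t)
    return idx


def estimate_pse(
    record: StaircaseRecord, method: str = "reversals"
) -> EquivalencePoint:
    """Point of subjective equality for one staircase.

    ``method='reversals'`` (default): mean of the reversal eccentricities
    after discarding the first two reversals; requires at least four
    reversals. ``method='tail_mean'``: mean of the last half of the
    trajectory (sensitivity-analysis alternative).
    """
    if method == "reversals":
        if len(record.reversals) < MIN_REVERSALS:
            raise StaircaseError(
                f"staircase {record.spec.mapping} level {record.spec.level} "
                f"produced only {len(record.reversals)} reversals (< "
                f"{MIN_REVERSALS}): it never converged"
            )
        eccs = record.reversal_eccentricities()[DISCARD_REVERSALS:]
        pse = float(np.mean(eccs))
    elif method == "tail_mean":
        n = len(record.trajectory)
        pse = float(np.mean(record.trajectory[n // 2:]))
    else:
        raise ValueError(f"unknown PSE method {method!r}")
    pse = float(np.clip(pse, ECC_MIN, ECC_MAX))
    return EquivalencePoint(
        fixed=record.spec.fixed,
        variable=EccContrastPair(pse, record.spec.variable_contrast),
        mapping=record.spec.mapping,
        level=record.spec.level,
    )


def preference_midpoint(
    observer: ObserverModel,
    spec: StaircaseSpec,
    resolution: float = 0.01,
) -> float:
    """Grid-search oracle: eccentricity where P(choose variable) crosses 0.5.

    Scans the stimulus range at ``resolution`` degrees and returns the point
    where the probability of choosing the variable target is nearest 0.5.
    Independent of the staircase dynamics; used to validate PSE estimates.
    """
    grid = np.arange(ECC_MIN, ECC_MAX + resolution / 2, resolution)
    probs = np.array(
        [
            1.0
            - choice_probability(
                observer, spec.fixed, EccContrastPair(float(e), spec.variable_contrast)
            )
            for e in grid
        ]
    )
    return float(grid[np.argmin(np.abs(probs - 0.5))])
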