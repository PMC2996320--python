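"""End-to-end experiment pipeline for one or many synthetic observers.

Stages, mirroring the two-session protocol: simulate calibration (1620
2AFC trials), fit the three true sensitivity curves by maximum likelihood,
build the 12 interleaved staircases and 180 dominance trials from the fits,
run the decision phase, then apply the equivalence / transitivity /
dominance battery and the expected-gain accounting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as vio
from .conjoint import (
    DominanceResult,
    EquivalenceTestResult,
    GainReport,
    TransitivityStatistics,
    dominance_test,
    equivalence_test,
    expected_gain_loss,
    transitivity_test,
)
from .observer import (
    ContrastLevel,
    ObserverModel,
    generate_calibration_design,
    generate_dominance_design,
    make_observer,
    simulate_calibration,
    veridical_observer,
)
from .psychometric import FitResult, fit_psychometric
from .staircase import build_staircase_specs, estimate_pse, run_decision_phase

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "summarize_cohort"]

logger = logging.getLogger("visconjoint")


@dataclass
class ExperimentConfig:
    """Configuration for one simulated observer's experiment.

    Defaults reproduce the protocol exactly: 1620 calibration trials, 12
    staircases of 70 trials (840), 90 + 90 dominance trials, 10,000
    bootstrap resamples. ``fast`` drops the bootstrap to 500 resamples for
    scaled runs.
    """

    observer: dict | None = None  # JSON-style observer config; default veridical
    seed: int = 0
    n_boot: int = 10_000
    fast: bool = False
    reward: float = 5.0
    pse_method: str = "reversals"
    refit_calibration: bool = True
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.fast:
            self.n_boot = min(self.n_boot, 500)

    def build_observer(self) -> ObserverModel:
        if self.observer is None:
            return veridical_observer(seed=self.seed)
        return make_observer(self.observer, seed=self.seed)


@dataclass
class ExperimentReport:
    """All per-observer results of one simulated experiment."""

    seed: int
    fits: dict[ContrastLevel, FitResult]
    equivalence: EquivalenceTestResult
    transitivity: TransitivityStatistics
    dominance: dict[str, DominanceResult]
    gain: GainReport
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def all_fits_converged(self) -> bool:
        return all(f.converged for f in self.fits.values())

    def to_dict(self) -> dict:
        return _jsonable(
            {
                "seed": self.seed,
                "fits": {
                    level.name: {
                        "tau": f.curve.tau,
                        "beta": f.curve.beta,
                        "log_likelihood": f.log_likelihood,
                        "n_trials": f.n_trials,
                        "converged": f.converged,
                    }
                    for level, f in self.fits.items()
                },
                "equivalence": {
                    "pairs": [
                        {
                            "mapping": f"{p.point.mapping[0].name}->{p.point.mapping[1].name}",
                            "level": p.point.level,
                            "fixed_eccentricity": p.point.fixed.eccentricity,
                            "pse": p.point.variable.eccentricity,
                            "dp": p.dp,
                            "ci": list(p.ci),
                            "significant": p.significant,
                            "ecc_error": p.ecc_error,
                        }
                        for p in self.equivalence.pairs
                    ],
                    "mean_signed_dp": self.equivalence.mean_signed_dp,
                    "t_p_value": self.equivalence.t_p_value,
                    "median_abs_ecc_error": self.equivalence.median_abs_ecc_error,
                    "n_boot": self.equivalence.n_boot,
                },
                "transitivity": {
                    "a": self.transitivity.a,
                    "b": self.transitivity.b,
                    "ci_a": list(self.transitivity.ci_a),
                    "ci_b": list(self.transitivity.ci_b),
                    "intransitive": self.transitivity.intransitive,
                    "n_boot": self.transitivity.n_boot,
                },
                "dominance": {
                    k: dataclasses.asdict(v) for k, v in self.dominance.items()
                },
                "gain": dataclasses.asdict(self.gain),
                "counts": self.counts,
            }
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full simulate -> calibrate -> decide -> test pipeline."""
    observer = config.build_observer()
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("observer seed=%d: calibration", config.seed)
    design = generate_calibration_design(rng=observer.rng)
    calibration = simulate_calibration(observer, design)
    if out_dir is not None:
        vio.calibration_to_csv(calibration, out_dir / "calibration.csv")

    logger.info("observer seed=%d: fitting sensitivity curves", config.seed)
    fits: dict[ContrastLevel, FitResult] = {}
    for level in ContrastLevel:
        sub = [t for t in calibration if t.contrast == level]
        fits[level] = fit_psychometric(
            [t.eccentricity for t in sub], [t.correct for t in sub]
        )
        logger.info(
            "  %s: tau=%.3f beta=%.3f (converged=%s)",
            level.name, fits[level].curve.tau, fits[level].curve.beta,
            fits[level].converged,
        )
    curves = {level: f.curve for level, f in fits.items()}
    if out_dir is not None:
        vio.fits_to_json(fits, out_dir / "fits.json")

    logger.info("observer seed=%d: decision phase", config.seed)
    specs = build_staircase_specs(curves)
    dominance_stubs = generate_dominance_design(curves)
    records, dominance_trials, trial_log = run_decision_phase(
        observer, specs, dominance_stubs
    )
    if out_dir is not None:
        vio.staircase_records_to_csv(records, out_dir / "staircases.csv")
        vio.decision_trials_to_csv(trial_log, out_dir / "decision_trials.csv")

    logger.info("observer seed=%d: test battery (B=%d)", config.seed, config.n_boot)
    points = [estimate_pse(r, method=config.pse_method) for r in records]
    analysis_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2**16 + 1])
    )
    equivalence = equivalence_test(
        points, records, calibration, curves,
        n_boot=config.n_boot, rng=analysis_rng,
        refit_calibration=config.refit_calibration,
    )
    transitivity = transitivity_test(
        records, n_boot=config.n_boot, rng=analysis_rng,
        pse_method=config.pse_method,
    )
    dominance = dominance_test(dominance_trials)
    gain = expected_gain_loss(trial_log, curves, reward=config.reward)

    report = ExperimentReport(
        seed=config.seed,
        fits=fits,
        equivalence=equivalence,
        transitivity=transitivity,
        dominance=dominance,
        gain=gain,
        counts={
            "calibration_trials": len(calibration),
            "staircase_trials": sum(len(r.trajectory) for r in records),
            "dominance_trials": len(dominance_trials),
            "decision_trials": len(trial_log),
        },
    )
    if out_dir is not None:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return report


def summarize_cohort(reports: list[ExperimentReport]) -> dict:
    """Median summaries across observers (converged fits only)."""
    if not reports:
        raise ValueError("need at least one report")
    usable = [r for r in reports if r.all_fits_converged]
    if not usable:
        raise ValueError("no observer had fully converged calibration fits")

    def med(values):
        return float(np.median(values))

    return {
        "n_observers": len(reports),
        "n_converged": len(usable),
        "median_abs_ecc_error": med(
            [r.equivalence.median_abs_ecc_error for r in usable]
        ),
        "median_a": med([r.transitivity.a for r in usable]),
        "median_b": med([r.transitivity.b for r in usable]),
        "n_intransitive": sum(r.transitivity.intransitive for r in usable),
        "median_equi_contrast_error_rate": med(
            [r.dominance["EQUI_CONTRAST"].rate for r in usable]
        ),
        "median_equi_eccentricity_error_rate": med(
            [r.dominance["EQUI_ECCENTRICITY"].rate for r in usable]
        ),
        "median_loss_fraction": med([r.gain.loss_fraction for r in usable]),
    }
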