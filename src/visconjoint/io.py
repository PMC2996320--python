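"""CSV trial logs and JSON reports/configs.

Trial logs are plain CSV with a mandatory header row; eccentricities are
written with four decimal places. Observer configs and analysis reports are
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .observer import CalibrationTrial, ContrastLevel, DecisionTrial, EccContrastPair
from .psychometric import FitResult
from .staircase import StaircaseRecord

__all__ = [
    "calibration_to_csv",
    "calibration_from_csv",
    "staircase_records_to_csv",
    "decision_trials_to_csv",
    "decision_trials_from_csv",
    "fits_to_json",
    "load_observer_config",
]

_FLOAT_FMT = "%.4f"


def calibration_to_csv(trials: list[CalibrationTrial], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "block": [t.block for t in trials],
            "contrast": [t.contrast.name for t in trials],
            "eccentricity": [t.eccentricity for t in trials],
            "stimulus": [t.stimulus for t in trials],
            "response": [t.response for t in trials],
            "correct": [t.correct for t in trials],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def calibration_from_csv(path: str | Path) -> list[CalibrationTrial]:
    df = pd.read_csv(path)
    return [
        CalibrationTrial(
            block=int(row.block),
            contrast=ContrastLevel[row.contrast],
            eccentricity=float(row.eccentricity),
            stimulus=str(row.stimulus),
            response=str(row.response),
            correct=bool(row.correct),
        )
        for row in df.itertuples()
    ]


def staircase_records_to_csv(
    records: list[StaircaseRecord], path: str | Path
) -> None:
    rows = []
    for sid, rec in enumerate(records):
        rev = set(rec.reversals)
        for t, (ecc, choice) in enumerate(zip(rec.trajectory, rec.choices)):
            rows.append(
                {
                    "staircase_id": sid,
                    "mapping": f"{rec.spec.mapping[0].name}->{rec.spec.mapping[1].name}",
                    "level": rec.spec.level,
                    "trial_index_within": t,
                    "variable_eccentricity": float(ecc),
                    "choice": choice,
                    "is_reversal": t in rev,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def decision_trials_to_csv(trials: list[DecisionTrial], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "trial_index_global": range(len(trials)),
            "origin": [t.origin for t in trials],
            "fixed_eccentricity": [t.pair_fixed.eccentricity for t in trials],
            "fixed_contrast": [t.pair_fixed.contrast.name for t in trials],
            "variable_eccentricity": [t.pair_variable.eccentricity for t in trials],
            "variable_contrast": [t.pair_variable.contrast.name for t in trials],
            "choice": [t.choice for t in trials],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def decision_trials_from_csv(path: str | Path) -> list[DecisionTrial]:
    df = pd.read_csv(path)
    return [
        DecisionTrial(
            pair_fixed=EccContrastPair(
                float(row.fixed_eccentricity), ContrastLevel[row.fixed_contrast]
            ),
            pair_variable=EccContrastPair(
                float(row.variable_eccentricity),
                ContrastLevel[row.variable_contrast],
            ),
            origin=str(row.origin),
            choice=str(row.choice),
        )
        for row in df.itertuples()
    ]


def fits_to_json(fits: dict[ContrastLevel, FitResult], path: str | Path) -> None:
    payload = {
        level.name: {
            "contrast": level.name,
            "tau": f.curve.tau,
            "beta": f.curve.beta,
            "log_likelihood": f.log_likelihood,
            "n_trials": f.n_trials,
            "converged": f.converged,
        }
        for level, f in fits.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_observer_config(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
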