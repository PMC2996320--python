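import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import visconjoint as vc
from visconjoint.observer import DEFAULT_TRUE_MAP, ContrastLevel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def true_curves():
    return dict(DEFAULT_TRUE_MAP)


@pytest.fixture(scope="session")
def calibrated(true_curves):
    """One veridical observer's calibration data and fitted curves."""
    observer = vc.veridical_observer(seed=11)
    design = vc.generate_calibration_design(rng=observer.rng)
    calibration = vc.simulate_calibration(observer, design)
    fits = {}
    for level in ContrastLevel:
        sub = [t for t in calibration if t.contrast == level]
        fits[level] = vc.fit_psychometric(
            [t.eccentricity for t in sub], [t.correct for t in sub]
        )
    return {
        "observer": observer,
        "calibration": calibration,
        "fits": fits,
        "curves": {k: f.curve for k, f in fits.items()},
    }


@pytest.fixture(scope="session")
def decision_run(calibrated):
    """The same observer's full decision phase (staircases + dominance)."""
    observer = calibrated["observer"]
    curves = calibrated["curves"]
    specs = vc.build_staircase_specs(curves)
    stubs = vc.generate_dominance_design(curves)
    records, dominance, log = vc.run_decision_phase(observer, specs, stubs)
    points = [vc.estimate_pse(r) for r in records]
    return {
        "records": records,
        "dominance": dominance,
        "log": log,
        "points": points,
    }
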