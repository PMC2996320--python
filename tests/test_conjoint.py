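"""Equivalence / transitivity / dominance tests and expected-gain accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

import visconjoint as vc
from visconjoint.conjoint import (
    EquivalenceTransform,
    analytic_transform,
    bootstrap_pses,
    dominance_test,
    equivalence_test,
    expected_gain_loss,
    fit_equivalence_transform,
    transitivity_statistics,
    transitivity_test,
)
from visconjoint.observer import (
    CONTRAST_CYCLE,
    DEFAULT_TRUE_MAP,
    ContrastLevel,
    DecisionTrial,
    EccContrastPair,
    generate_dominance_design,
)
from visconjoint.psychometric import PsychometricCurve, invert, predict
from visconjoint.staircase import (
    ANCHOR_LEVELS,
    EquivalencePoint,
    build_staircase_specs,
    run_decision_phase,
)

taus = st.floats(min_value=3.0, max_value=9.0)
betas = st.floats(min_value=1.0, max_value=4.0)


def _noiseless_points(curve_from, curve_to, mapping, levels=ANCHOR_LEVELS):
    """Exact equivalence points: PSE solves p_to(e) = p_from(anchor)."""
    points = []
    for level in levels:
        e_fixed = invert(curve_from, level)
        pse = brentq(
            lambda e: predict(curve_to, e) - predict(curve_from, e_fixed),
            1e-6, 1e3, xtol=1e-12,
        )
        points.append(
            EquivalencePoint(
                fixed=EccContrastPair(e_fixed, mapping[0]),
                variable=EccContrastPair(pse, mapping[1]),
                mapping=mapping,
                level=level,
            )
        )
    return points


class TestEquivalenceTransform:
    def test_equal_beta_pair_gives_slope_one_intercept_log_tau_ratio(self):
        c1 = PsychometricCurve(tau=5.0, beta=2.0)
        c2 = PsychometricCurve(tau=8.0, beta=2.0)
        # anchors for this pair must stay in range: use levels near the top
        points = _noiseless_points(
            c1, c2, CONTRAST_CYCLE[0], levels=(0.75, 0.8, 0.85, 0.9)
        )
        tf = fit_equivalence_transform(points)
        assert tf.slope == pytest.approx(1.0, abs=1e-9)
        assert tf.intercept == pytest.approx(math.log(8.0 / 5.0), abs=1e-9)

    def test_slope_equals_beta_ratio(self):
        c1 = PsychometricCurve(tau=5.0, beta=2.0)
        c2 = PsychometricCurve(tau=5.0, beta=1.0)
        # levels where both anchors and their images stay inside [2, 12.2]
        points = _noiseless_points(
            c1, c2, CONTRAST_CYCLE[0], levels=(0.6, 0.65, 0.7, 0.75)
        )
        tf = fit_equivalence_transform(points)
        assert tf.slope == pytest.approx(2.0, abs=1e-6)

    def test_identical_curves_give_identity_transform(self):
        c = PsychometricCurve(tau=6.0, beta=2.5)
        points = _noiseless_points(c, c, CONTRAST_CYCLE[0])
        tf = fit_equivalence_transform(points)
        assert tf.slope == pytest.approx(1.0, abs=1e-9)
        assert tf.intercept == pytest.approx(0.0, abs=1e-9)

    @given(tau1=taus, beta1=betas, tau2=taus, beta2=betas)
    def test_analytic_transform_matches_root_finding(self, tau1, beta1, tau2, beta2):
        c1 = PsychometricCurve(tau=tau1, beta=beta1)
        c2 = PsychometricCurve(tau=tau2, beta=beta2)
        tf = analytic_transform(ContrastLevel.LOW, ContrastLevel.MED, c1, c2)
        # probe at performance levels where both curves have usable slope;
        # far tails are numerically flat and defeat the root-finding oracle
        for p in (0.6, 0.75, 0.9):
            e1 = invert(c1, p)
            e2 = brentq(lambda e: predict(c2, e) - p, 1e-9, 1e3, xtol=1e-12)
            assert tf.apply(e1) == pytest.approx(e2, rel=1e-8)

    def test_requires_distinct_fixed_eccentricities(self):
        pt = EquivalencePoint(
            fixed=EccContrastPair(5.0, ContrastLevel.LOW),
            variable=EccContrastPair(6.0, ContrastLevel.MED),
            mapping=CONTRAST_CYCLE[0],
            level=0.7,
        )
        with pytest.raises(ValueError):
            fit_equivalence_transform([pt, pt])


class TestTransitivityStatistics:
    def test_identity_transforms_compose_to_zero(self):
        tfs = [
            EquivalenceTransform(src, dst, 0.0, 1.0)
            for src, dst in CONTRAST_CYCLE
        ]
        assert transitivity_statistics(*tfs) == (0.0, 0.0)

    def test_slope_product_arithmetic(self):
        tfs = [
            EquivalenceTransform(src, dst, 0.0, 1.2)
            for src, dst in CONTRAST_CYCLE
        ]
        a, b = transitivity_statistics(*tfs)
        assert a == pytest.approx(0.0)
        assert b == pytest.approx(1.2**3 - 1.0)

    def test_non_cyclic_labels_rejected(self):
        tfs = [
            EquivalenceTransform(src, dst, 0.0, 1.0)
            for src, dst in CONTRAST_CYCLE
        ]
        with pytest.raises(ValueError):
            transitivity_statistics(tfs[1], tfs[0], tfs[2])

    @given(
        t1=taus, b1=betas, t2=taus, b2=betas, t3=taus, b3=betas
    )
    def test_any_consistent_subjective_triple_is_transitive(
        self, t1, b1, t2, b2, t3, b3
    ):
        """Transforms induced by one curve triple compose to the identity."""
        curves = {
            ContrastLevel.LOW: PsychometricCurve(tau=t1, beta=b1),
            ContrastLevel.MED: PsychometricCurve(tau=t2, beta=b2),
            ContrastLevel.HIGH: PsychometricCurve(tau=t3, beta=b3),
        }
        tfs = [
            analytic_transform(src, dst, curves[src], curves[dst])
            for src, dst in CONTRAST_CYCLE
        ]
        a, b = transitivity_statistics(*tfs)
        assert abs(a) < 1e-9
        assert abs(b) < 1e-9

    def test_noiseless_pse_pipeline_is_transitive(self):
        """Exact PSEs from any subjective triple give (a, b) = (0, 0)."""
        curves = {
            ContrastLevel.LOW: PsychometricCurve(tau=4.5, beta=2.0),
            ContrastLevel.MED: PsychometricCurve(tau=6.5, beta=2.4),
            ContrastLevel.HIGH: PsychometricCurve(tau=8.0, beta=3.0),
        }
        tfs = []
        for src, dst in CONTRAST_CYCLE:
            pts = _noiseless_points(curves[src], curves[dst], (src, dst))
            tfs.append(fit_equivalence_transform(pts))
        a, b = transitivity_statistics(*tfs)
        assert abs(a) < 1e-9
        assert abs(b) < 1e-9


class TestTransitivityBootstrap:
    def test_veridical_observer_rarely_flagged(self, calibrated):
        flags = 0
        for seed in range(10):
            obs = vc.veridical_observer(seed=300 + seed)
            records, _, _ = run_decision_phase(
                obs,
                build_staircase_specs(calibrated["curves"]),
                generate_dominance_design(calibrated["curves"]),
            )
            stats = transitivity_test(
                records, n_boot=400, rng=np.random.default_rng(seed)
            )
            flags += stats.intransitive
        assert flags <= 2

    def test_corkscrew_observer_detected_with_positive_b(self, calibrated):
        detected = 0
        for seed in range(10):
            obs = vc.corkscrew_observer(seed=400 + seed, composite_slope=2.0)
            records, _, _ = run_decision_phase(
                obs,
                build_staircase_specs(calibrated["curves"]),
                generate_dominance_design(calibrated["curves"]),
            )
            stats = transitivity_test(
                records, n_boot=400, rng=np.random.default_rng(seed)
            )
            detected += stats.intransitive and stats.ci_b[0] > 0
        assert detected >= 8

    def test_bootstrap_interval_contains_point_estimate(self, decision_run):
        stats = transitivity_test(
            decision_run["records"], n_boot=300, rng=np.random.default_rng(0)
        )
        assert stats.ci_a[0] <= stats.a <= stats.ci_a[1]
        assert stats.ci_b[0] <= stats.b <= stats.ci_b[1]

    def test_intervals_widen_with_shorter_staircases(self, calibrated):
        """Halving staircase length should not shrink the bootstrap
        intervals for (a, b) on average."""
        widths = {}
        for n_trials in (70, 24):
            spans = []
            for seed in range(4):
                obs = vc.veridical_observer(seed=500 + seed)
                specs = vc.build_staircase_specs(
                    calibrated["curves"], n_trials=n_trials
                )
                records, _, _ = run_decision_phase(
                    obs, specs, generate_dominance_design(calibrated["curves"])
                )
                stats = transitivity_test(
                    records, n_boot=300, rng=np.random.default_rng(seed)
                )
                spans.append(
                    (stats.ci_a[1] - stats.ci_a[0])
                    + (stats.ci_b[1] - stats.ci_b[0])
                )
            widths[n_trials] = np.mean(spans)
        assert widths[24] > widths[70]

    def test_small_bootstrap_warns(self, calibrated, decision_run):
        with pytest.warns(UserWarning, match="unstable"):
            equivalence_test(
                decision_run["points"],
                decision_run["records"],
                calibrated["calibration"],
                calibrated["curves"],
                n_boot=50,
                rng=np.random.default_rng(0),
            )

    def test_bootstrap_pses_concentrate_near_observed_pse(self, decision_run):
        rec = decision_run["records"][0]
        pse = vc.estimate_pse(rec).variable.eccentricity
        boot = bootstrap_pses(rec, 400, np.random.default_rng(1))
        assert abs(np.median(boot) - pse) <= 2 * rec.spec.step


class TestEquivalenceTest:
    def test_probability_gap_of_worked_pair(self, true_curves):
        """A pair judged equal at true probabilities 0.93 vs 0.61 scores
        a signed probability difference of 0.32."""
        low, med = true_curves[ContrastLevel.LOW], true_curves[ContrastLevel.MED]
        point = EquivalencePoint(
            fixed=EccContrastPair(invert(low, 0.93), ContrastLevel.LOW),
            variable=EccContrastPair(invert(med, 0.61), ContrastLevel.MED),
            mapping=CONTRAST_CYCLE[0],
            level=0.9,
        )
        from visconjoint.conjoint import _signed_dp

        assert abs(_signed_dp(point, true_curves)) == pytest.approx(0.32, abs=1e-12)

    def test_veridical_observer_shows_no_patterned_failure(
        self, calibrated, decision_run
    ):
        res = equivalence_test(
            decision_run["points"],
            decision_run["records"],
            calibrated["calibration"],
            calibrated["curves"],
            n_boot=300,
            rng=np.random.default_rng(5),
        )
        assert len(res.pairs) == 12
        assert sum(p.significant for p in res.pairs) == 0
        assert abs(res.mean_signed_dp) < 0.05
        assert res.median_abs_ecc_error < 1.0

    def test_contrast_underestimator_has_same_sign_dps(self, calibrated):
        """An observer who underestimates the contrast effect produces
        signed probability differences that all share one sign."""
        obs = vc.contrast_misjudging_observer(seed=21, tau_scale=0.5)
        records, _, _ = run_decision_phase(
            obs,
            build_staircase_specs(calibrated["curves"]),
            generate_dominance_design(calibrated["curves"]),
        )
        points = [vc.estimate_pse(r) for r in records]
        res = equivalence_test(
            points, records, calibrated["calibration"], calibrated["curves"],
            n_boot=200, rng=np.random.default_rng(3),
        )
        signs = {np.sign(p.dp) for p in res.pairs}
        assert len(signs) == 1
        assert res.t_p_value < 0.05

    def test_type_one_error_rate_is_controlled(self, true_curves):
        """Family-wise false-positive rate of the 12 Bonferroni-corrected
        pair tests stays near the nominal 5% for veridical observers."""
        from visconjoint.observer import (
            generate_calibration_design,
            simulate_calibration,
        )
        from visconjoint.psychometric import fit_psychometric

        familywise = 0
        n_obs = 12
        for seed in range(n_obs):
            obs = vc.veridical_observer(seed=600 + seed)
            calib = simulate_calibration(
                obs, generate_calibration_design(rng=obs.rng)
            )
            fits = {}
            for level in ContrastLevel:
                sub = [t for t in calib if t.contrast == level]
                fits[level] = fit_psychometric(
                    [t.eccentricity for t in sub], [t.correct for t in sub]
                ).curve
            records, _, _ = run_decision_phase(
                obs, build_staircase_specs(fits), generate_dominance_design(fits)
            )
            points = [vc.estimate_pse(r) for r in records]
            res = equivalence_test(
                points, records, calib, fits,
                n_boot=300, rng=np.random.default_rng(800 + seed),
            )
            familywise += any(p.significant for p in res.pairs)
        assert familywise <= 2  # nominal 5% of 12


class TestDominance:
    def test_closed_form_beta_interval(self):
        res = dominance_test(_dominance_trials(errors_c=0, errors_e=15))
        ci = res["EQUI_CONTRAST"].ci
        # Beta(1, 31) has closed-form quantiles 1 - (1-q)^(1/31)
        assert ci[0] == pytest.approx(1 - 0.975 ** (1 / 31), rel=1e-9)
        assert ci[1] == pytest.approx(1 - 0.025 ** (1 / 31), rel=1e-9)
        assert ci[0] == pytest.approx(0.0008, abs=2e-4)
        assert ci[1] == pytest.approx(0.112, abs=2e-3)
        assert res["EQUI_CONTRAST"].rate == 0.0

    def test_half_errors_interval_spans_half(self):
        res = dominance_test(_dominance_trials(errors_c=15, errors_e=15))
        r = res["EQUI_CONTRAST"]
        assert r.rate == 0.5
        assert r.ci[0] < 0.5 < r.ci[1]

    def test_matches_scipy_beta_quantiles(self):
        res = dominance_test(_dominance_trials(errors_c=4, errors_e=7))
        for cond, errors in (("EQUI_CONTRAST", 4), ("EQUI_ECCENTRICITY", 7)):
            lo, hi = beta_dist.ppf([0.025, 0.975], errors + 1, 30 - errors + 1)
            assert res[cond].ci == pytest.approx((lo, hi))

    def test_low_error_rate_upper_bound_below_chance(self):
        res = dominance_test(_dominance_trials(errors_c=6, errors_e=6))
        for r in res.values():
            assert r.ci[1] < 0.5

    def test_deterministic_veridical_observer_makes_no_errors(self, true_curves):
        obs = vc.veridical_observer(seed=0, noise=math.inf)
        stubs = generate_dominance_design(true_curves)
        done = []
        for t in stubs:
            raw = vc.simulate_choice(obs, t.pair_fixed, t.pair_variable)
            done.append(
                DecisionTrial(
                    pair_fixed=t.pair_fixed,
                    pair_variable=t.pair_variable,
                    origin=t.origin,
                    choice="FIXED" if raw == "FIRST" else "VARIABLE",
                )
            )
        res = dominance_test(done)
        assert res["EQUI_CONTRAST"].errors == 0
        assert res["EQUI_ECCENTRICITY"].errors == 0

    def test_malformed_trial_rejected(self):
        bad = DecisionTrial(
            pair_fixed=EccContrastPair(4.0, ContrastLevel.LOW),
            pair_variable=EccContrastPair(6.0, ContrastLevel.MED),
            origin="EQUI_CONTRAST",
            choice="FIXED",
        )
        with pytest.raises(ValueError):
            dominance_test([bad] * 30 + _dominance_trials(0, 0)[30:])


class TestGain:
    def test_worked_single_trial_loss(self, true_curves):
        """Choosing the 0.61 target over the 0.93 target forfeits $1.60."""
        low, med = true_curves[ContrastLevel.LOW], true_curves[ContrastLevel.MED]
        trial = DecisionTrial(
            pair_fixed=EccContrastPair(invert(med, 0.93), ContrastLevel.MED),
            pair_variable=EccContrastPair(invert(low, 0.61), ContrastLevel.LOW),
            origin="STAIRCASE",
            choice="VARIABLE",
        )
        report = expected_gain_loss([trial], true_curves, reward=5.0)
        loss = report.ideal_expected_gain - report.actual_expected_gain
        assert loss == pytest.approx(1.60, abs=1e-9)
        assert report.loss_fraction == pytest.approx(1.60 / (0.93 * 5.0), abs=1e-9)

    def test_all_optimal_chooser_loses_nothing(self, true_curves, decision_run):
        optimal = []
        for t in decision_run["log"]:
            p_f = predict(true_curves[t.pair_fixed.contrast], t.pair_fixed.eccentricity)
            p_v = predict(
                true_curves[t.pair_variable.contrast], t.pair_variable.eccentricity
            )
            optimal.append(
                DecisionTrial(
                    pair_fixed=t.pair_fixed,
                    pair_variable=t.pair_variable,
                    origin=t.origin,
                    choice="FIXED" if p_f >= p_v else "VARIABLE",
                )
            )
        report = expected_gain_loss(optimal, true_curves)
        assert report.loss_fraction == 0.0

    def test_matches_bruteforce_enumeration(self, true_curves, decision_run):
        trials = decision_run["log"]
        report = expected_gain_loss(trials, true_curves, reward=5.0)
        ideal = actual = 0.0
        for t in trials:
            p = {
                "FIXED": predict(
                    true_curves[t.pair_fixed.contrast], t.pair_fixed.eccentricity
                ),
                "VARIABLE": predict(
                    true_curves[t.pair_variable.contrast],
                    t.pair_variable.eccentricity,
                ),
            }
            ideal += max(p.values()) * 5.0
            actual += p[t.choice] * 5.0
        assert report.loss_fraction == pytest.approx(
            (ideal - actual) / ideal, abs=1e-12
        )


def _dominance_trials(errors_c: int, errors_e: int) -> list[DecisionTrial]:
    """30-trial dominance sets per condition with prescribed error counts."""
    trials = []
    for i in range(30):
        # equi-contrast: fixed is nearer (better); error = choose variable
        trials.append(
            DecisionTrial(
                pair_fixed=EccContrastPair(4.0, ContrastLevel.MED),
                pair_variable=EccContrastPair(8.0, ContrastLevel.MED),
                origin="EQUI_CONTRAST",
                choice="VARIABLE" if i < errors_c else "FIXED",
            )
        )
    for i in range(30):
        # equi-eccentricity: fixed is higher contrast; error = choose variable
        trials.append(
            DecisionTrial(
                pair_fixed=EccContrastPair(6.0, ContrastLevel.HIGH),
                pair_variable=EccContrastPair(6.0, ContrastLevel.LOW),
                origin="EQUI_ECCENTRICITY",
                choice="VARIABLE" if i < errors_e else "FIXED",
            )
        )
    return trials
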