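"""Discrimination, Brier, calibration, decision-curve, and consistency metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pssval as pv
from pssval.data_model import HorizonStatus, PredictionSet
from pssval.metrics import (
    auc_at_horizon,
    brier_score,
    calibration_fit,
    decision_curve,
    model_consistency,
)

from conftest import statuses_from_counts, statuses_from_string


def series(values, prefix="P"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


def pairwise_auc_oracle(values: np.ndarray, alive: np.ndarray) -> float:
    """O(n^2) concordance count: every (alive, dead) pair, ties half."""
    total = 0.0
    pairs = 0
    for i in np.flatnonzero(alive):
        for j in np.flatnonzero(~alive):
            pairs += 1
            if values[i] > values[j]:
                total += 1.0
            elif values[i] == values[j]:
                total += 0.5
    return total / pairs


class TestAUC:
    def test_hand_example(self):
        # alive: 0.6, 0.3 ; dead: 0.2, 0.4 -> 3 of 4 pairs concordant
        values = series([0.6, 0.3, 0.2, 0.4])
        statuses = statuses_from_string("aadd")
        est = auc_at_horizon(values, statuses, ci_method="hanley")
        assert est.value == pytest.approx(0.75)
        assert est.n_effective == 4

    def test_perfect_separation(self):
        est = auc_at_horizon(
            series([0.9, 0.8, 0.1, 0.2]), statuses_from_string("aadd"),
            ci_method="hanley",
        )
        assert est.value == 1.0

    def test_constant_predictions_are_coin_flip(self):
        est = auc_at_horizon(
            series([0.5] * 6), statuses_from_string("aaddda"), ci_method="hanley"
        )
        assert est.value == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            auc_at_horizon(series([0.5, 0.6]), statuses_from_string("aa"))

    def test_unknown_dropped(self):
        full = auc_at_horizon(
            series([0.6, 0.3, 0.2, 0.4]), statuses_from_string("aadd"),
            ci_method="hanley",
        )
        with_unknown = auc_at_horizon(
            series([0.6, 0.3, 0.2, 0.4, 0.99]), statuses_from_string("aaddu"),
            ci_method="hanley",
        )
        assert with_unknown.value == full.value
        assert with_unknown.n_effective == 4

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            values = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            alive = rng.random(n) < 0.5
            if alive.all() or not alive.any():
                continue
            fast = auc_at_horizon(
                series(values),
                statuses_from_string("".join("a" if a else "d" for a in alive)),
                ci_method="hanley",
            ).value
            assert fast == pytest.approx(pairwise_auc_oracle(values, alive), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        values = rng.random(n)
        alive = rng.random(n) < 0.5
        if alive.all() or not alive.any():
            return
        statuses = statuses_from_string("".join("a" if a else "d" for a in alive))
        a1 = auc_at_horizon(series(values), statuses, ci_method="hanley").value
        a2 = auc_at_horizon(
            series(np.exp(3 * values) + 1), statuses, ci_method="hanley"
        ).value
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_bootstrap_ci_brackets_and_is_reproducible(self):
        rng = np.random.default_rng(3)
        values = series(rng.random(60))
        statuses = statuses_from_counts(25, 35)
        e1 = auc_at_horizon(values, statuses, n_boot=200, seed=9)
        e2 = auc_at_horizon(values, statuses, n_boot=200, seed=9)
        assert (e1.ci_low, e1.value, e1.ci_high) == (e2.ci_low, e2.value, e2.ci_high)
        assert e1.ci_low <= e1.value <= e1.ci_high


class TestBrier:
    def test_perfect_predictions_score_zero(self):
        res = brier_score(series([1.0, 1.0, 0.0]), statuses_from_string("aad"))
        assert res.brier.value == 0.0

    def test_null_brier_from_12_month_counts(self):
        """167 deaths among 326 ascertained -> null model Brier 0.25 (2 dp)."""
        res = brier_score(
            series([0.5] * 326), statuses_from_counts(167, 159)
        )
        assert res.null_brier == pytest.approx((167 / 326) * (159 / 326))
        assert round(res.null_brier, 2) == 0.25

    def test_constant_prevalence_prediction_equals_null(self):
        statuses = statuses_from_counts(3, 7)
        pbar = 7 / 10
        res = brier_score(series([pbar] * 10), statuses)
        assert res.brier.value == pytest.approx(res.null_brier, abs=1e-15)
        assert res.improvement == pytest.approx(0.0, abs=1e-15)

    def test_requires_probabilities(self):
        with pytest.raises(ValueError):
            brier_score(series([3.0, 5.0]), statuses_from_string("ad"))


class TestCalibration:
    def test_log_oe_zero_when_observed_equals_expected(self):
        statuses = statuses_from_counts(5, 5)
        values = series([0.5] * 10)
        res = calibration_fit(values, statuses, ci_method="none")
        assert res.log_oe.value == pytest.approx(0.0)

    def test_log_oe_closed_form(self):
        """O = 159 survivors, E = 101.5 expected -> ln(159/101.5) ~ 0.449."""
        assert np.log(159 / 101.5) == pytest.approx(0.449, abs=5e-4)
        rng = np.random.default_rng(0)
        statuses = statuses_from_counts(167, 159)
        # constant prediction with sum = 101.5 over 326 patients
        values = series([101.5 / 326] * 326)
        res = calibration_fit(values, statuses, ci_method="none")
        assert res.observed_survivors == 159
        assert res.expected_survivors == pytest.approx(101.5)
        assert res.log_oe.value == pytest.approx(np.log(159 / 101.5), abs=1e-12)

    def test_constant_predictions_leave_slope_undefined(self):
        res = calibration_fit(
            series([0.4] * 10), statuses_from_counts(4, 6), ci_method="none"
        )
        assert res.slope is None
        assert np.isfinite(res.intercept.value)
        assert np.isfinite(res.log_oe.value)

    def test_identity_predictions_recover_zero_one(self, default_study):
        """p_hat = true probability -> intercept ~ 0, slope ~ 1 at large n."""
        import pssval.synthetic_cohort as sc

        n = 20000
        cfg = pv.SimulationConfig(n_patients=n, target_ascertained=(n,) * 6)
        study = pv.generate_cohort(cfg, seed=3)
        statuses = pv.ascertain_statuses(study.cohort, 12.0)
        res = calibration_fit(
            study.truth.survival_probs[12.0], statuses, ci_method="none"
        )
        assert res.intercept.value == pytest.approx(0.0, abs=0.05)
        assert res.slope.value == pytest.approx(1.0, abs=0.05)

    def test_positive_shift_means_underestimated_survival(self):
        """Generator shift +0.8 (model underestimates survival) -> intercept ~ +0.8."""
        n = 20000
        cfg = pv.SimulationConfig(n_patients=n, target_ascertained=(n,) * 6)
        study = pv.generate_cohort(cfg, seed=4)
        pred = pv.simulate_predictions(
            study.truth, pv.PredictionSimSpec("m", calibration_shift=0.8), seed=5
        )
        statuses = pv.ascertain_statuses(study.cohort, 12.0)
        res = calibration_fit(pred.values[12.0], statuses, ci_method="none")
        assert res.intercept.value == pytest.approx(0.8, abs=0.1)
        assert res.log_oe.value > 0  # underestimation on the O:E scale too

    def test_log_oe_sign_matches_intercept_sign(self):
        n = 20000
        cfg = pv.SimulationConfig(n_patients=n, target_ascertained=(n,) * 6)
        study = pv.generate_cohort(cfg, seed=6)
        statuses = pv.ascertain_statuses(study.cohort, 12.0)
        for shift in (-1.0, 1.0):
            pred = pv.simulate_predictions(
                study.truth, pv.PredictionSimSpec("m", calibration_shift=shift), seed=7
            )
            res = calibration_fit(pred.values[12.0], statuses, ci_method="none")
            assert np.sign(res.intercept.value) == np.sign(shift)
            assert np.sign(res.log_oe.value) == np.sign(shift)

    def test_curve_fractions_in_unit_interval(self):
        rng = np.random.default_rng(8)
        p = rng.random(200)
        alive = rng.random(200) < p
        statuses = statuses_from_string("".join("a" if a else "d" for a in alive))
        res = calibration_fit(series(p), statuses, ci_method="none")
        assert len(res.curve) >= 5
        for _, frac, n in res.curve:
            assert 0.0 <= frac <= 1.0
            assert n > 0


class TestDecisionCurve:
    def test_hand_enumerated_example(self):
        """n=4, alive=(1,1,0,0), p_hat=(.8,.4,.6,.2), p_t=.5 -> nb = 0."""
        values = series([0.8, 0.4, 0.6, 0.2])
        statuses = statuses_from_string("aadd")
        dc = decision_curve(values, statuses, threshold_grid=np.array([0.5]))
        assert dc.nb_model[0] == pytest.approx(0.0)

    def test_treat_all_approaches_prevalence_at_low_threshold(self):
        values = series([0.8, 0.4, 0.6, 0.2])
        statuses = statuses_from_string("aadd")
        dc = decision_curve(values, statuses, threshold_grid=np.array([1e-6]))
        assert dc.nb_all[0] == pytest.approx(0.5, abs=1e-5)

    def test_treat_none_is_identically_zero(self):
        values = series([0.8, 0.4, 0.6, 0.2])
        statuses = statuses_from_string("aadd")
        dc = decision_curve(values, statuses)
        assert np.all(dc.nb_none == 0.0)

    def test_perfect_model_dominates_treat_all(self):
        rng = np.random.default_rng(1)
        alive = rng.random(200) < 0.5
        values = series(alive.astype(float))  # survival prob = truth
        statuses = statuses_from_string("".join("a" if a else "d" for a in alive))
        dc = decision_curve(values, statuses)
        prevalence = (~alive).mean()
        assert np.all(dc.nb_model <= prevalence + 1e-12)
        assert np.all(dc.nb_model >= dc.nb_all - 1e-12)
        assert np.all(dc.nb_model >= 0.0)

    def test_grid_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            decision_curve(
                series([0.5, 0.5]), statuses_from_string("ad"),
                threshold_grid=np.array([0.0, 0.5]),
            )


class TestModelConsistency:
    def _pred(self, rows, horizons):
        return PredictionSet(
            model_name="m", mode="probability",
            values=pd.DataFrame(
                rows, index=[f"P{i}" for i in range(len(rows))], columns=horizons
            ),
        )

    def test_worked_patient_is_flagged(self):
        """34% at 6 months but 37% at 12 months violates attrition by time."""
        pred = self._pred([[0.34, 0.37]], [6.0, 12.0])
        res = model_consistency(pred)
        assert res.overall == 0.0
        assert res.violations[0][:3] == ("P0", 6.0, 12.0)

    def test_monotone_predictions_are_fully_consistent(self):
        pred = self._pred([[0.9, 0.6, 0.2], [0.8, 0.8, 0.1]], [3.0, 6.0, 12.0])
        res = model_consistency(pred)
        assert res.overall == 1.0
        assert all(v == 1.0 for v in res.pair_mc.values())

    def test_two_of_three_pairs_reasonable(self):
        pred = self._pred([[0.9, 0.5], [0.4, 0.6], [0.7, 0.7]], [6.0, 12.0])
        res = model_consistency(pred)
        assert res.overall == pytest.approx(2 / 3)
        assert res.n_reasonable == 2 and res.n_pairs == 3

    def test_ties_count_as_reasonable(self):
        pred = self._pred([[0.5, 0.5]], [6.0, 12.0])
        assert model_consistency(pred).overall == 1.0

    def test_single_horizon_errors(self):
        pred = self._pred([[0.5]], [6.0])
        with pytest.raises(ValueError, match="2 horizons"):
            model_consistency(pred)

    def test_missing_cells_skip_pairs(self):
        pred = self._pred([[0.9, np.nan, 0.2], [0.8, 0.5, 0.6]], [3.0, 6.0, 12.0])
        res = model_consistency(pred)
        # P0 contributes only (3,12); P1 all three pairs; 3 reasonable of 4
        assert res.n_pairs == 4
        assert res.n_reasonable == 3

    def test_sorting_each_patient_restores_full_consistency(self):
        rng = np.random.default_rng(11)
        raw = rng.random((20, 4))
        pred = self._pred(np.sort(raw, axis=1)[:, ::-1], [1.0, 3.0, 6.0, 12.0])
        assert model_consistency(pred).overall == 1.0

    def test_score_mode_rejected(self):
        pred = PredictionSet(
            model_name="m", mode="score",
            values=pd.DataFrame({3.0: [1.0], 12.0: [2.0]}, index=["P0"]),
        )
        with pytest.raises(ValueError, match="probability"):
            model_consistency(pred)
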