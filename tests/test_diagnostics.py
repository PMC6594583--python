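"""Confusion metrics, ROC, threshold selection, lasso, subgroup analyses."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from egmscore import (
    ConfusionCounts,
    RunConfig,
    confusion_at_threshold,
    difficult_case_analysis,
    evaluate_probability_threshold,
    evaluate_records,
    fit_lasso_logistic,
    metrics_from_counts,
    roc,
    roc_from_scores,
    select_threshold_cost_benefit,
    select_threshold_youden,
    subgroup_accuracy,
    summarize_features,
)
from egmscore.diagnostics import LassoFit
from egmscore.errors import EgmWarning, ParameterError, ValidationError
from egmscore.estimators import LassoLogisticRefinement

# strategy for a labelled score sample containing both classes, with ties
scores_and_labels = st.lists(
    st.tuples(
        st.integers(min_value=0, max_value=20),  # coarse grid -> many ties
        st.booleans(),
    ),
    min_size=4,
    max_size=60,
).filter(lambda xs: len({y for _, y in xs}) == 2)


def _mw_concordance(scores, y01):
    """Brute-force tie-adjusted Mann-Whitney concordance."""
    pos = [s for s, y in zip(scores, y01) if y]
    neg = [s for s, y in zip(scores, y01) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_matches_per_record_tally(self, cohort):
        records = cohort[:20]
        counts = confusion_at_threshold(records, 3.1)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for rec in records:
            pred = rec.features.composite_score > 3.1
            if pred and rec.successful:
                tally["tp"] += 1
            elif pred:
                tally["fp"] += 1
            elif rec.successful:
                tally["fn"] += 1
            else:
                tally["tn"] += 1
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (
            tally["tp"], tally["fp"], tally["fn"], tally["tn"]
        )

    def test_all_scores_above_threshold(self, cohort):
        counts = confusion_at_threshold(cohort[:50], 0.0)
        assert counts.fn == 0 and counts.tn == 0

    def test_missing_scores_listed(self, cohort):
        bare = type(cohort[0])(**{**cohort[0].__dict__, "features": None})
        with pytest.raises(ValidationError, match=bare.signal_id):
            confusion_at_threshold([bare] + cohort[:5], 3.1)


class TestMetrics:
    def test_published_operating_point(self):
        # 2x2 counts of the validation cohort at threshold 3.1
        m = metrics_from_counts(ConfusionCounts(tp=122, fp=54, fn=19, tn=152))
        assert round(m.sensitivity, 2) == 0.87
        assert round(m.specificity, 2) == 0.74
        assert round(m.npv, 2) == 0.89
        assert round(m.ppv, 2) == 0.69  # 122/176
        assert m.accuracy == pytest.approx(274 / 347)

    def test_perfect_classifier(self):
        m = metrics_from_counts(ConfusionCounts(tp=5, fp=0, fn=0, tn=7))
        assert all(v == 1.0 for v in m.to_dict().values())

    def test_symmetric_counts_give_one_half(self):
        m = metrics_from_counts(ConfusionCounts(tp=1, fp=1, fn=1, tn=1))
        assert all(v == 0.5 for v in m.to_dict().values())

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            metrics_from_counts(ConfusionCounts(0, 0, 0, 0))

    def test_zero_denominator_marks_metric_nan(self):
        m = metrics_from_counts(ConfusionCounts(tp=0, fp=0, fn=3, tn=5))
        assert math.isnan(m.ppv)

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_accuracy_is_prevalence_weighted_mix(self, tp, fp, fn, tn):
        counts = ConfusionCounts(tp, fp, fn, tn)
        if counts.total == 0 or counts.n_positive == 0 or counts.n_negative == 0:
            return
        m = metrics_from_counts(counts)
        prevalence = counts.n_positive / counts.total
        assert m.accuracy == pytest.approx(
            prevalence * m.sensitivity + (1 - prevalence) * m.specificity
        )


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        curve = roc_from_scores(
            np.array([5.0, 6.0, 1.0, 2.0]), np.array([1, 1, 0, 0])
        )
        assert curve.auc == pytest.approx(1.0)

    def test_identical_scores_give_auc_half(self):
        curve = roc_from_scores(np.full(10, 3.0), np.array([1] * 5 + [0] * 5))
        assert curve.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_from_scores(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_curve_is_monotone(self, cohort):
        curve = roc(cohort)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.thresholds) < 0)

    @given(scores_and_labels)
    def test_auc_equals_mann_whitney_concordance(self, data):
        scores = np.array([s for s, _ in data], dtype=float)
        y = np.array([y for _, y in data], dtype=int)
        curve = roc_from_scores(scores, y)
        assert curve.auc == pytest.approx(_mw_concordance(scores, y), abs=1e-12)

    def test_auc_agrees_with_sklearn(self, cohort):
        from sklearn.metrics import roc_auc_score

        scores = np.array([r.features.composite_score for r in cohort])
        y = np.array([r.successful for r in cohort], dtype=int)
        assert roc(cohort).auc == pytest.approx(roc_auc_score(y, scores))


class TestThresholdSelection:
    def test_two_point_toy_picks_larger_j(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 0, 1, 1])
        choice = select_threshold_youden(roc_from_scores(scores, y))
        # J is maximal (1.0) only for threshold 2.0
        assert choice.threshold == pytest.approx(2.0)
        assert choice.objective == pytest.approx(1.0)

    def test_matches_exhaustive_grid_scan(self, cohort):
        scores = np.array([r.features.composite_score for r in cohort])
        y = np.array([r.successful for r in cohort], dtype=int)
        curve = roc_from_scores(scores, y)
        choice = select_threshold_youden(curve)

        best_j, best_t = -np.inf, None
        for t in np.concatenate([np.unique(scores), [-np.inf]]):
            tpr = ((scores > t) & (y == 1)).sum() / (y == 1).sum()
            fpr = ((scores > t) & (y == 0)).sum() / (y == 0).sum()
            j = tpr - fpr
            if j > best_j + 1e-12 or (
                abs(j - best_j) <= 1e-12 and (best_t is None or t > best_t)
            ):
                best_j, best_t = j, t
        assert choice.threshold == pytest.approx(best_t)
        assert choice.objective == pytest.approx(best_j)

    def test_degenerate_curve_returns_highest_threshold(self):
        curve = roc_from_scores(np.full(6, 2.0), np.array([1, 0] * 3))
        choice = select_threshold_youden(curve)
        assert choice.threshold == pytest.approx(2.0)
        assert choice.objective == pytest.approx(0.0)

    @given(scores_and_labels)
    def test_unit_ratio_reduces_to_youden(self, data):
        scores = np.array([s for s, _ in data], dtype=float)
        y = np.array([y for _, y in data], dtype=int)
        curve = roc_from_scores(scores, y)
        youden = select_threshold_youden(curve)
        cb = select_threshold_cost_benefit(curve, 1.0)
        assert cb.threshold == youden.threshold
        assert cb.objective == pytest.approx(youden.objective)

    @given(scores_and_labels, st.floats(min_value=1.0, max_value=10.0))
    def test_threshold_non_decreasing_in_ratio(self, data, ratio):
        scores = np.array([s for s, _ in data], dtype=float)
        y = np.array([y for _, y in data], dtype=int)
        curve = roc_from_scores(scores, y)
        low = select_threshold_cost_benefit(curve, 1.0)
        high = select_threshold_cost_benefit(curve, ratio)
        assert high.threshold >= low.threshold

    def test_youden_is_prevalence_invariant(self, cohort):
        records = cohort[:120]
        negatives = [r for r in records if not r.successful]
        doubled = records + negatives
        t1 = select_threshold_youden(roc(records)).threshold
        t2 = select_threshold_youden(roc(doubled)).threshold
        assert t1 == pytest.approx(t2)

    def test_non_positive_ratio_rejected(self, cohort):
        with pytest.raises(ParameterError):
            select_threshold_cost_benefit(roc(cohort), 0.0)

    def test_single_interior_point_selected_for_any_ratio(self):
        scores = np.array([1.0, 1.0, 2.0, 2.0])
        y = np.array([0, 0, 1, 1])
        curve = roc_from_scores(scores, y)
        for ratio in (0.5, 1.0, 3.0):
            choice = select_threshold_cost_benefit(curve, ratio)
            assert choice.threshold == pytest.approx(1.0)


class TestLasso:
    def test_informative_predictor_kept_noise_shrunk(self, rng):
        n = 400
        y = rng.integers(0, 2, n)
        mu = np.where(y == 1, 1.686, 0.833)
        X = pd.DataFrame({
            "gender": rng.choice(["male", "female"], n),
            "hf_to_r_time": np.exp(rng.normal(4.8, 0.2, n)),
            "hf_to_lf_time": np.exp(rng.normal(4.0, 0.2, n)),
            "lf_to_r_time": rng.normal(70, 24, n),
            "chd": rng.random(n) < 0.05,
            "ap_side": rng.choice(["left", "right"], n),
            "lf_integral": np.exp(rng.normal(2.0, 0.5, n)),
            "hf_integral_total": np.exp(rng.normal(2.0, 0.5, n)),
            "composite_score": np.exp(mu + rng.normal(0, 0.55, n)),
        })
        model = LassoLogisticRefinement(
            Cs=8, cv_folds=5, random_state=1
        ).fit(X, y)
        coefs = dict(zip(model.predictor_names_, model.coef_))
        assert coefs["composite_score"] > 0
        noise = [v for k, v in coefs.items() if k != "composite_score"]
        # most chance-correlated covariates are removed exactly; any
        # survivors carry only small weights
        assert sum(v == 0.0 for v in noise) >= len(noise) - 3
        assert max(abs(v) for v in noise) < 0.25

    def test_infinite_regularization_limit(self, rng):
        n = 300
        y = (rng.random(n) < 0.3).astype(int)
        X = pd.DataFrame({
            "composite_score": np.exp(rng.normal(1.0, 0.5, n)),
            "lf_integral": np.exp(rng.normal(2.0, 0.5, n)),
        })
        model = LassoLogisticRefinement(
            predictors=["composite_score", "lf_integral"],
            Cs=[1e-4], cv_folds=3, random_state=0,
        ).fit(X, y)
        assert np.all(model.coef_ == 0.0)
        prevalence = y.mean()
        assert model.intercept_ == pytest.approx(
            math.log(prevalence / (1 - prevalence)), abs=0.01
        )

    def test_weak_regularization_matches_unpenalized_fit(self, rng):
        import statsmodels.api as sm

        n = 250
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        logit = 0.8 * x1 - 0.5 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        X = pd.DataFrame({"a": x1, "b": x2})
        model = LassoLogisticRefinement(
            predictors=["a", "b"], log_features=(),
            Cs=[1e6], cv_folds=3, random_state=0,
        ).fit(X, y)
        probs = model.predict_proba(X)[:, 1]

        Z = (X - X.mean()) / X.std(ddof=0)
        oracle = sm.Logit(y, sm.add_constant(Z.to_numpy())).fit(disp=0)
        np.testing.assert_allclose(probs, oracle.predict(), atol=1e-3)

    def test_constant_predictor_dropped_with_warning(self, rng):
        n = 120
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({
            "composite_score": np.exp(
                np.where(y == 1, 1.7, 0.8) + rng.normal(0, 0.5, n)
            ),
            "chd": np.zeros(n, dtype=bool),
        })
        with pytest.warns(EgmWarning, match="constant"):
            model = LassoLogisticRefinement(
                predictors=["composite_score", "chd"],
                Cs=4, cv_folds=3, random_state=0,
            ).fit(X, y)
        assert model.dropped_ == ["chd"]
        assert model.predictor_names_ == ["composite_score"]

    def test_cohort_fit_reproducible_under_seed(self, cohort):
        cfg = RunConfig(rng_seed=5, cv_folds=5)
        fit1 = fit_lasso_logistic(cohort, cfg)
        fit2 = fit_lasso_logistic(cohort, cfg)
        assert fit1.coefficients == fit2.coefficients
        np.testing.assert_array_equal(fit1.probabilities, fit2.probabilities)

    def test_probability_threshold_evaluation(self, cohort):
        cfg = RunConfig(rng_seed=5, cv_folds=5)
        fit = fit_lasso_logistic(cohort, cfg)
        choice = evaluate_probability_threshold(fit, "youden")
        assert 0.0 < choice.threshold < 1.0
        assert choice.metrics is not None
        # oracle: exhaustive scan of the probability grid
        best = max(
            ((fit.probabilities > t) & (fit.outcomes == 1)).sum()
            / (fit.outcomes == 1).sum()
            - ((fit.probabilities > t) & (fit.outcomes == 0)).sum()
            / (fit.outcomes == 0).sum()
            for t in np.unique(fit.probabilities)
        )
        assert choice.objective == pytest.approx(best)

    def test_perfect_probabilities_saturate_metrics(self):
        outcomes = np.array([1, 0, 1, 0, 1])
        fit = LassoFit(
            predictor_names=[], coefficients={}, intercept=0.0, C=1.0,
            probabilities=outcomes.astype(float), outcomes=outcomes,
            cv_folds=2, seed=0,
        )
        choice = evaluate_probability_threshold(fit, "youden")
        assert choice.metrics.sensitivity == 1.0
        assert choice.metrics.specificity == 1.0

    def test_constant_probabilities_rejected(self):
        outcomes = np.array([1, 0, 1, 0])
        fit = LassoFit(
            predictor_names=[], coefficients={}, intercept=0.0, C=1.0,
            probabilities=np.full(4, 0.5), outcomes=outcomes,
            cv_folds=2, seed=0,
        )
        with pytest.raises(ValidationError):
            evaluate_probability_threshold(fit, "youden")


class TestSubgroupsAndDifficultCases:
    def test_subgroup_matches_per_record_tally(self, cohort):
        table = subgroup_accuracy(cohort, "ap_side", threshold=3.1)
        for _, row in table.iterrows():
            subset = [
                r for r in cohort
                if (r.ap_side if r.ap_side is not None else "missing")
                == row["group"]
            ]
            correct = sum(
                (r.features.composite_score > 3.1) == r.successful
                for r in subset
            )
            assert row["n"] == len(subset)
            assert row["accuracy"] == pytest.approx(correct / len(subset))

    def test_single_group_equals_overall_accuracy(self, cohort):
        records = [r for r in cohort if r.ap_side == "left"]
        table = subgroup_accuracy(records, "ap_side", threshold=3.1)
        assert len(table) == 1
        counts = confusion_at_threshold(records, 3.1)
        overall = metrics_from_counts(counts).accuracy
        assert table.iloc[0]["accuracy"] == pytest.approx(overall)

    def test_unknown_key_rejected(self, cohort):
        with pytest.raises(ParameterError):
            subgroup_accuracy(cohort, "shoe_size")

    def test_small_groups_flagged(self, cohort):
        table = subgroup_accuracy(cohort, "chd", min_n=10_000)
        assert table["small_group"].all()

    def test_difficult_selection_matches_brute_force(self, cohort):
        result = difficult_case_analysis(cohort, threshold=3.1)
        lesions = {r.patient_id: r.lesions_in_case for r in cohort}
        median = float(np.median(list(lesions.values())))
        expected = [
            r for r in cohort if lesions[r.patient_id] > median
        ]
        assert result.median_lesions == median
        assert result.n_signals == len(expected)
        assert result.n_patients == len({r.patient_id for r in expected})

    def test_all_single_lesion_patients_give_empty_set(self, cohort):
        records = []
        for rec in cohort[:10]:
            records.append(
                type(rec)(**{**rec.__dict__, "lesions_in_case": 1})
            )
        result = difficult_case_analysis(records)
        assert result.n_signals == 0

    def test_missing_lesion_counts_rejected(self, cohort):
        bad = type(cohort[0])(**{**cohort[0].__dict__, "lesions_in_case": None})
        with pytest.raises(ValidationError):
            difficult_case_analysis([bad] + cohort[:5])


class TestSummary:
    def test_single_record_per_class_has_zero_iqr_width(self, cohort):
        one_each = [
            next(r for r in cohort if r.successful),
            next(r for r in cohort if not r.successful),
        ]
        table = summarize_features(one_each)
        skewed = table[table["kind"] == "median_iqr"]
        assert (skewed["spread_high"] == skewed["spread_low"]).all()

    def test_matches_quantile_oracle(self, cohort):
        table = summarize_features(cohort)
        scores = sorted(
            r.features.composite_score for r in cohort if r.successful
        )
        # linear-interpolation (type 7) quantiles from the sorted sample
        def q(p):
            h = (len(scores) - 1) * p
            lo = int(math.floor(h))
            return scores[lo] + (h - lo) * (scores[min(lo + 1, len(scores) - 1)] - scores[lo])

        row = table[
            (table["feature"] == "composite_score")
            & (table["outcome"] == "successful")
        ].iloc[0]
        assert row["center"] == pytest.approx(q(0.5))
        assert row["spread_low"] == pytest.approx(q(0.25))
        assert row["spread_high"] == pytest.approx(q(0.75))

    def test_empty_class_rejected(self, cohort):
        successes = [r for r in cohort if r.successful]
        with pytest.raises(ValidationError):
            summarize_features(successes)


def test_clustered_bootstrap_auc_ci(cohort):
    from egmscore.diagnostics import auc_confidence_interval

    point = roc(cohort).auc
    lo, hi = auc_confidence_interval(cohort, n_boot=200, seed=3)
    assert 0.5 < lo < point < hi <= 1.0
    assert (lo, hi) == auc_confidence_interval(cohort, n_boot=200, seed=3)


def test_full_report_structure(cohort):
    report = evaluate_records(cohort, RunConfig(rng_seed=2, cv_folds=5))
    assert report["n_signals"] == len(cohort)
    assert set(report["metrics"]) == {
        "sensitivity", "specificity", "ppv", "npv", "accuracy"
    }
    assert 0.5 < report["auc"] <= 1.0
    assert "youden" in report["threshold_choices"]
    assert "difficult_ablations" in report
    assert "lasso" in report
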