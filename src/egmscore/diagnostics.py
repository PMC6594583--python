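"""Diagnostic evaluation of the signal score and its statistical refinement.

Confusion metrics, ROC/AUC, Youden and cost-benefit threshold selection,
the lasso-logistic refinement, subgroup accuracy, difficult-ablation
analysis and per-class feature summaries.

Conventions
-----------
* The positive class is a *successful* signal; classification everywhere is
  ``score > threshold`` (strict).
* The ROC is traced over all unique score values (thresholds descending,
  ending at -inf); its trapezoid area equals the tie-adjusted Mann-Whitney
  concordance exactly.
* Threshold-selection ties resolve to the higher (more specific) threshold.
* Quantiles use linear interpolation (type 7), which the reported IQR
  endpoints depend on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ParameterError, ValidationError
from .features import SUCCESSFUL, classify_signal
from .io import COVARIATE_COLUMNS, FEATURE_COLUMNS, SignalRecord, records_to_frame


@dataclass
class ConfusionCounts:
    """2x2 counts at an operating threshold (positive = successful)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


@dataclass
class DiagnosticMetrics:
    """Operating-point metrics; a metric with a zero denominator is NaN."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float

    def to_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


@dataclass
class ROCCurve:
    """ROC over all unique score thresholds (descending, last = -inf)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class ThresholdChoice:
    """A selected operating threshold and the metrics achieved there."""

    method: str
    threshold: float
    objective: float
    ratio: float | None = None
    metrics: DiagnosticMetrics | None = None


@dataclass
class LassoFit:
    """Fitted lasso-logistic refinement with per-signal probabilities."""

    predictor_names: list[str]
    coefficients: dict[str, float]
    intercept: float
    C: float
    probabilities: np.ndarray
    outcomes: np.ndarray  # 1 = successful
    cv_folds: int
    seed: int
    dropped: list[str] = field(default_factory=list)
    encodings: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# confusion metrics


def _scores_outcomes(records: list[SignalRecord]) -> tuple[np.ndarray, np.ndarray]:
    missing = [r.signal_id for r in records if r.composite_score is None
               or not math.isfinite(r.composite_score)]
    if missing:
        raise ValidationError(
            f"records without a composite score: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    scores = np.array([r.composite_score for r in records], dtype=float)
    y = np.array([r.successful for r in records], dtype=int)
    return scores, y


def confusion_at_threshold(
    records: list[SignalRecord], threshold: float = 3.1
) -> ConfusionCounts:
    """Tally calls against outcomes at ``score > threshold``."""
    scores, y = _scores_outcomes(records)
    pred = np.array(
        [classify_signal(s, threshold) == SUCCESSFUL for s in scores], dtype=int
    )
    return ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
    )


def metrics_from_counts(counts: ConfusionCounts) -> DiagnosticMetrics:
    """Closed-form operating-point metrics from 2x2 counts."""
    if counts.total == 0:
        raise ValidationError("all confusion counts are zero")

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return DiagnosticMetrics(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
        accuracy=(counts.tp + counts.tn) / counts.total,
    )


# ---------------------------------------------------------------------------
# ROC and threshold selection


def roc_from_scores(scores: np.ndarray, y01: np.ndarray) -> ROCCurve:
    """ROC of ``score > t`` over all unique score values.

    Built explicitly (rather than via a library) so the strict-inequality
    classification convention and the tie geometry are exactly those of the
    classifier; ties in scores produce diagonal segments, and the trapezoid
    area equals tie-adjusted Mann-Whitney concordance.
    """
    scores = np.asarray(scores, dtype=float)
    y01 = np.asarray(y01, dtype=int)
    n_pos = int(y01.sum())
    n_neg = int(len(y01) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC requires both outcome classes")
    uniq = np.unique(scores)[::-1]
    # counts per unique value, descending
    pos_counts = np.array([(y01[scores == v] == 1).sum() for v in uniq])
    neg_counts = np.array([(y01[scores == v] == 0).sum() for v in uniq])
    tpr = np.concatenate([[0.0], np.cumsum(pos_counts) / n_pos])
    fpr = np.concatenate([[0.0], np.cumsum(neg_counts) / n_neg])
    thresholds = np.concatenate([uniq, [-np.inf]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def roc(records: list[SignalRecord]) -> ROCCurve:
    """ROC of the composite score over a labelled cohort."""
    scores, y = _scores_outcomes(records)
    return roc_from_scores(scores, y)


def _select(curve: ROCCurve, weight: float, method: str, ratio=None) -> ThresholdChoice:
    objective = curve.tpr - weight * curve.fpr
    idx = int(np.argmax(objective))  # first max = highest threshold
    return ThresholdChoice(
        method=method,
        threshold=float(curve.thresholds[idx]),
        objective=float(objective[idx]),
        ratio=ratio,
    )


def select_threshold_youden(curve: ROCCurve) -> ThresholdChoice:
    """Threshold maximizing Youden's J = TPR - FPR (prevalence-free)."""
    return _select(curve, 1.0, "youden")


def select_threshold_cost_benefit(curve: ROCCurve, ratio: float) -> ThresholdChoice:
    """Threshold maximizing TPR - ratio*FPR.

    ``ratio`` > 1 weights false positives (wasted lesions) more than missed
    true positives, shifting the cut toward higher specificity; ratio 1
    reduces to Youden's criterion.
    """
    if ratio <= 0:
        raise ParameterError(f"cost-benefit ratio must be > 0, got {ratio}")
    return _select(curve, ratio, "cost_benefit", ratio=ratio)


def auc_confidence_interval(
    records: list[SignalRecord],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling whole patients.

    Signals within a patient are correlated (repeated lesions at one
    substrate), so the bootstrap resamples patient clusters, not signals.
    Replicates where resampling leaves a single outcome class are redrawn.
    """
    by_patient: dict[str, list[SignalRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    patients = list(by_patient)
    rng = np.random.default_rng(seed)
    aucs = []
    while len(aucs) < n_boot:
        sample: list[SignalRecord] = []
        for pid in rng.choice(patients, size=len(patients), replace=True):
            sample.extend(by_patient[pid])
        outcomes = {r.outcome for r in sample}
        if len(outcomes) < 2:
            continue
        aucs.append(roc(sample).auc)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# lasso refinement


def fit_lasso_logistic(
    records: list[SignalRecord], config: RunConfig | None = None
) -> LassoFit:
    """Fit the L1-regularized logistic refinement on a labelled cohort.

    Predictors are the a-priori set (gender, HF-to-R, HF-to-LF and LF-to-R
    times, CHD, pathway side, LF/HF integrals, composite score), with skewed
    continuous predictors log-transformed.  The penalty is chosen by
    cross-validation stratified by outcome and grouped by patient.
    """
    from .estimators import LassoLogisticRefinement

    config = config or RunConfig()
    frame = records_to_frame(records)
    y = np.array([r.successful for r in records], dtype=int)
    groups = frame["patient_id"].to_numpy()
    model = LassoLogisticRefinement(
        cv_folds=config.cv_folds, random_state=config.rng_seed
    ).fit(frame, y, groups=groups)
    proba = model.predict_proba(frame)[:, 1]
    coefficients = dict(zip(model.predictor_names_, model.coef_.tolist()))
    return LassoFit(
        predictor_names=model.predictor_names_,
        coefficients=coefficients,
        intercept=model.intercept_,
        C=model.C_,
        probabilities=proba,
        outcomes=y,
        cv_folds=config.cv_folds,
        seed=config.rng_seed,
        dropped=model.dropped_,
        encodings=model.encodings_,
    )


def evaluate_probability_threshold(
    fit: LassoFit, method: str = "youden", ratio: float = 1.5
) -> ThresholdChoice:
    """Select and evaluate an operating threshold on the probability scale."""
    if np.unique(fit.probabilities).size < 2:
        raise ValidationError(
            "predicted probabilities are constant; the ROC is degenerate"
        )
    curve = roc_from_scores(fit.probabilities, fit.outcomes)
    if method == "youden":
        choice = select_threshold_youden(curve)
    elif method == "cost_benefit":
        choice = select_threshold_cost_benefit(curve, ratio)
    else:
        raise ParameterError(f"unknown selection method {method!r}")
    pred = fit.probabilities > choice.threshold
    counts = ConfusionCounts(
        tp=int((pred & (fit.outcomes == 1)).sum()),
        fp=int((pred & (fit.outcomes == 0)).sum()),
        fn=int((~pred & (fit.outcomes == 1)).sum()),
        tn=int((~pred & (fit.outcomes == 0)).sum()),
    )
    choice.metrics = metrics_from_counts(counts)
    return choice


# ---------------------------------------------------------------------------
# subgroup and difficult-ablation analyses


def subgroup_accuracy(
    records: list[SignalRecord],
    key: str,
    threshold: float = 3.1,
    min_n: int = 10,
) -> pd.DataFrame:
    """Fraction of signals classified correctly within each level of ``key``.

    Returns a DataFrame (group, n, n_correct, accuracy, small_group); levels
    with fewer than ``min_n`` signals are flagged, not suppressed.  Records
    with a missing covariate value form a 'missing' group.
    """
    if key not in COVARIATE_COLUMNS:
        raise ParameterError(
            f"unknown covariate {key!r}; expected one of {COVARIATE_COLUMNS}"
        )
    scores, y = _scores_outcomes(records)
    correct = (scores > threshold).astype(int) == y
    labels = [getattr(r, key) for r in records]
    labels = ["missing" if v is None else str(v) for v in labels]
    rows = []
    for group in sorted(set(labels)):
        mask = np.array([v == group for v in labels])
        n = int(mask.sum())
        n_correct = int(correct[mask].sum())
        rows.append({
            "group": group,
            "n": n,
            "n_correct": n_correct,
            "accuracy": n_correct / n,
            "small_group": n < min_n,
        })
    return pd.DataFrame(rows)


@dataclass
class DifficultCaseResult:
    """Performance on signals from procedures needing many lesions."""

    median_lesions: float
    n_patients: int
    n_signals: int
    counts: ConfusionCounts
    metrics: DiagnosticMetrics


def difficult_case_analysis(
    records: list[SignalRecord], threshold: float = 3.1
) -> DifficultCaseResult:
    """Classification performance in difficult ablations.

    A difficult ablation is a procedure requiring strictly more than the
    cohort-median number of lesions; the median is taken over patients and
    all signals of the selected patients are pooled.
    """
    lesions: dict[str, int] = {}
    for r in records:
        if r.lesions_in_case is None:
            raise ValidationError(
                f"record {r.signal_id}: lesions_in_case is missing"
            )
        lesions[r.patient_id] = max(lesions.get(r.patient_id, 0), r.lesions_in_case)
    median = float(np.median(list(lesions.values())))
    difficult = {p for p, n in lesions.items() if n > median}
    subset = [r for r in records if r.patient_id in difficult]
    if not subset:
        return DifficultCaseResult(
            median_lesions=median, n_patients=0, n_signals=0,
            counts=ConfusionCounts(0, 0, 0, 0),
            metrics=DiagnosticMetrics(*(math.nan,) * 5),
        )
    counts = confusion_at_threshold(subset, threshold)
    return DifficultCaseResult(
        median_lesions=median,
        n_patients=len(difficult),
        n_signals=len(subset),
        counts=counts,
        metrics=metrics_from_counts(counts),
    )


# ---------------------------------------------------------------------------
# feature summaries


def summarize_features(
    records: list[SignalRecord],
    normal_features: tuple[str, ...] = ("lf_to_r_time",),
) -> pd.DataFrame:
    """Per-feature, per-class descriptive summary.

    Skewed features are summarized as median (IQR, linear-interpolation
    quantiles); features flagged in ``normal_features`` as mean +/- SD.  No
    significance tests are computed.
    """
    frame = records_to_frame(records)
    frame = frame[frame["composite_score"].notna()]
    rows = []
    for outcome in (SUCCESSFUL, "unsuccessful"):
        cls = frame[frame["outcome"] == outcome]
        if len(cls) == 0:
            raise ValidationError(f"no records in class {outcome!r}")
        for name in FEATURE_COLUMNS:
            values = cls[name].dropna().to_numpy(dtype=float)
            if values.size == 0:
                continue
            if name in normal_features:
                rows.append({
                    "feature": name, "outcome": outcome, "kind": "mean_sd",
                    "center": float(np.mean(values)),
                    "spread_low": float(np.mean(values) - np.std(values, ddof=1))
                    if values.size > 1 else float(np.mean(values)),
                    "spread_high": float(np.mean(values) + np.std(values, ddof=1))
                    if values.size > 1 else float(np.mean(values)),
                    "n": int(values.size),
                })
            else:
                q25, q50, q75 = np.quantile(values, [0.25, 0.5, 0.75])
                rows.append({
                    "feature": name, "outcome": outcome, "kind": "median_iqr",
                    "center": float(q50),
                    "spread_low": float(q25),
                    "spread_high": float(q75),
                    "n": int(values.size),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-cohort evaluation (the CLI / acceptance surface)


def evaluate_records(
    records: list[SignalRecord],
    config: RunConfig | None = None,
    with_lasso: bool = True,
) -> dict:
    """Full diagnostic report of a labelled cohort as a JSON-able dict."""
    config = config or RunConfig()
    thr = config.score_threshold
    counts = confusion_at_threshold(records, thr)
    metrics = metrics_from_counts(counts)
    curve = roc(records)
    youden = select_threshold_youden(curve)
    cb = select_threshold_cost_benefit(curve, config.cost_benefit_ratio)
    summary = summarize_features(records)

    def _choice_dict(choice: ThresholdChoice) -> dict:
        out = {
            "method": choice.method,
            "threshold": choice.threshold,
            "objective": choice.objective,
        }
        if choice.ratio is not None:
            out["ratio"] = choice.ratio
        if choice.metrics is not None:
            out["metrics"] = choice.metrics.to_dict()
        return out

    report = {
        "config": config.to_dict(),
        "n_signals": len(records),
        "n_successful": counts.n_positive,
        "n_unsuccessful": counts.n_negative,
        "threshold": thr,
        "confusion": {"tp": counts.tp, "fp": counts.fp,
                      "fn": counts.fn, "tn": counts.tn},
        "metrics": metrics.to_dict(),
        "auc": curve.auc,
        "threshold_choices": {
            "youden": _choice_dict(youden),
            "cost_benefit": _choice_dict(cb),
        },
        "feature_summary": summary.to_dict(orient="records"),
    }

    have_lesions = all(r.lesions_in_case is not None for r in records)
    if have_lesions:
        difficult = difficult_case_analysis(records, thr)
        report["difficult_ablations"] = {
            "median_lesions": difficult.median_lesions,
            "n_patients": difficult.n_patients,
            "n_signals": difficult.n_signals,
            "metrics": difficult.metrics.to_dict() if difficult.n_signals else None,
            "accuracy": difficult.metrics.accuracy if difficult.n_signals else None,
        }

    subgroups = {}
    for key in ("ap_side", "chd", "energy", "approach", "atrial_paced"):
        if any(getattr(r, key) is not None for r in records):
            subgroups[key] = subgroup_accuracy(
                records, key, threshold=thr, min_n=config.subgroup_min_n
            ).to_dict(orient="records")
    if subgroups:
        report["subgroups"] = subgroups

    if with_lasso:
        fit = fit_lasso_logistic(records, config)
        prob_curve = roc_from_scores(fit.probabilities, fit.outcomes)
        report["lasso"] = {
            "coefficients": fit.coefficients,
            "intercept": fit.intercept,
            "C": fit.C,
            "cv_folds": fit.cv_folds,
            "seed": fit.seed,
            "dropped": fit.dropped,
            "encodings": fit.encodings,
            "auc": prob_curve.auc,
            "youden": _choice_dict(
                evaluate_probability_threshold(fit, "youden")
            ),
            "cost_benefit": _choice_dict(
                evaluate_probability_threshold(
                    fit, "cost_benefit", config.cost_benefit_ratio
                )
            ),
        }
    return report
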