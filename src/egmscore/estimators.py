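"""Scikit-learn style estimators.

Three estimators cover the pipeline from raw traces to site calls:

* :class:`ElectrogramFeatureExtractor` — transformer turning electrogram
  recordings into the per-signal feature table;
* :class:`ScoreThresholdClassifier` — the operative classifier: a cut on the
  composite score (fixed at 3.1 by default, or refitted by Youden /
  cost-benefit threshold selection on training data);
* :class:`LassoLogisticRefinement` — L1-regularized logistic regression on
  the signal features, the statistical refinement the score is compared
  against.

All follow the fit/predict/transform contract with ``get_params`` /
``set_params``, so they compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from . import dsp
from .errors import EgmWarning, ParameterError, ValidationError
from .features import SUCCESSFUL, UNSUCCESSFUL, compute_features

#: continuous predictors whose cohort distributions are right-skewed and are
#: log-transformed before the regularized fit
DEFAULT_LOG_FEATURES = (
    "composite_score",
    "hf_integral_total",
    "hf_integral_windowed",
    "lf_integral",
    "hf_to_lf_time",
    "hf_to_r_time",
)

#: the a-priori predictor set of the logistic refinement
DEFAULT_PREDICTORS = (
    "gender",
    "hf_to_r_time",
    "hf_to_lf_time",
    "lf_to_r_time",
    "chd",
    "ap_side",
    "lf_integral",
    "hf_integral_total",
    "composite_score",
)


def _scores_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValidationError("expected a single score column")
    if not np.isfinite(x).all():
        raise ValidationError("scores contain non-finite values")
    return x


class ElectrogramFeatureExtractor(TransformerMixin, BaseEstimator):
    """Turn electrogram recordings into per-signal feature rows.

    ``transform`` accepts an iterable of
    :class:`~egmscore.io.ElectrogramRecording` and returns a DataFrame with
    one row per recording, columns named after
    :class:`~egmscore.features.SignalFeatures`.  If a recording's ``meta``
    carries ``energy_onset_ms``, the last complete beat before that time is
    selected; otherwise the whole export is treated as one analysis beat.
    """

    def __init__(
        self,
        split_freq_hz: float = 100.0,
        filter_order: int = 4,
        window_halfwidth_ms: float = 25.0,
        onset_k_sd: float = 3.0,
        onset_sustain_ms: float = 5.0,
        baseline_frac: float = 0.2,
        beat_shift_ms: float = 100.0,
        amplitude_mode: str = "absolute",
        score_scale: float = 1.0,
    ):
        self.split_freq_hz = split_freq_hz
        self.filter_order = filter_order
        self.window_halfwidth_ms = window_halfwidth_ms
        self.onset_k_sd = onset_k_sd
        self.onset_sustain_ms = onset_sustain_ms
        self.baseline_frac = baseline_frac
        self.beat_shift_ms = beat_shift_ms
        self.amplitude_mode = amplitude_mode
        self.score_scale = score_scale

    def fit(self, X=None, y=None):
        """Stateless; present for pipeline compatibility."""
        return self

    def transform_one(self, recording):
        """Features of a single recording (see class docstring)."""
        window = None
        onset = recording.meta.get("energy_onset_ms")
        if onset is not None:
            window = dsp.select_beat(
                recording, float(onset), beat_shift_ms=self.beat_shift_ms
            )
        beat = dsp.band_split(
            recording,
            split_freq_hz=self.split_freq_hz,
            filter_order=self.filter_order,
            beat_window=window,
        )
        landmarks = dsp.detect_landmarks(
            recording, beat,
            onset_k_sd=self.onset_k_sd,
            onset_sustain_ms=self.onset_sustain_ms,
            baseline_frac=self.baseline_frac,
        )
        return compute_features(
            beat, landmarks,
            window_halfwidth_ms=self.window_halfwidth_ms,
            amplitude_mode=self.amplitude_mode,
            score_scale=self.score_scale,
        )

    def transform(self, X) -> pd.DataFrame:
        rows = [self.transform_one(rec).to_dict() for rec in X]
        return pd.DataFrame(rows)


class ScoreThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Classify ablation signals by a cut on the composite score.

    A signal is called successful iff its score is *strictly* greater than
    the threshold.  With ``method='fixed'`` the configured threshold is used
    as-is; with ``'youden'`` or ``'cost_benefit'`` the threshold is selected
    on the training scores from the ROC curve (ties resolved toward the
    higher, more specific threshold).

    Attributes
    ----------
    threshold_ : float
        Operating threshold after ``fit``.
    roc_ : ROCCurve or None
        Training ROC (None for ``method='fixed'``).
    classes_ : ndarray
        ``[negative, positive]`` class labels; the positive class is
        'successful' (string labels) or the greater label otherwise.
    """

    def __init__(
        self,
        threshold: float = 3.1,
        method: str = "fixed",
        ratio: float = 1.5,
    ):
        self.threshold = threshold
        self.method = method
        self.ratio = ratio

    def _encode_y(self, y) -> tuple[np.ndarray, np.ndarray]:
        y = np.asarray(y)
        labels = set(np.unique(y).tolist())
        if labels <= {SUCCESSFUL, UNSUCCESSFUL}:
            classes = np.array([UNSUCCESSFUL, SUCCESSFUL], dtype=object)
        else:
            uniq = np.unique(y)
            if len(uniq) > 2:
                raise ValidationError(f"outcome is not binary: {uniq}")
            classes = uniq if len(uniq) == 2 else np.append(uniq, uniq)
        return classes, (y == classes[-1]).astype(int)

    def fit(self, X, y):
        from .diagnostics import (
            roc_from_scores,
            select_threshold_cost_benefit,
            select_threshold_youden,
        )

        scores = _scores_1d(X)
        self.classes_, y01 = self._encode_y(y)
        if self.method == "fixed":
            self.threshold_ = float(self.threshold)
            self.roc_ = None
        elif self.method in ("youden", "cost_benefit"):
            self.roc_ = roc_from_scores(scores, y01)
            if self.method == "youden":
                choice = select_threshold_youden(self.roc_)
            else:
                choice = select_threshold_cost_benefit(self.roc_, self.ratio)
            self.threshold_ = float(choice.threshold)
        else:
            raise ParameterError(
                f"method must be 'fixed', 'youden' or 'cost_benefit', "
                f"got {self.method!r}"
            )
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        return _scores_1d(X) - self.threshold_

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        positive = _scores_1d(X) > self.threshold_
        return np.where(positive, self.classes_[-1], self.classes_[0])


class LassoLogisticRefinement(ClassifierMixin, BaseEstimator):
    """L1-regularized logistic regression on the per-signal features.

    Continuous skewed predictors are log-transformed, all predictors are
    standardized, and the penalty strength is chosen by deviance-based
    cross-validation with folds stratified by outcome and (when ``groups``
    is passed to ``fit``) grouped by patient so repeated signals from one
    patient never straddle a fold boundary.  By default the one-standard-
    error rule picks the strongest penalty whose mean CV deviance is within
    one SE of the minimum (``selection='min'`` takes the minimum itself).

    Parameters
    ----------
    predictors : sequence of str, optional
        Columns of the fitted DataFrame to use; defaults to the a-priori
        set (gender, timing intervals, CHD, pathway side, LF/HF integrals,
        composite score).
    log_features : sequence of str
        Predictors log-transformed before standardization (values clipped
        below at 1e-6 to guard exact zeros).
    Cs : int or array-like
        Number of penalty strengths on a log grid (1e-2 .. 1e2), or the
        explicit grid of inverse penalty strengths.
    cv_folds : int
        Cross-validation folds.
    random_state : int
        Seed for fold shuffling.

    Attributes
    ----------
    coef_ : ndarray of shape (n_used_predictors,)
        Coefficients on the standardized (log) scale; exact zeros mark
        predictors removed by the penalty.
    intercept_ : float
    C_ : float
        Selected inverse penalty strength.
    predictor_names_ : list of str
        Predictors actually entering the fit (constants dropped).
    dropped_ : list of str
        Constant predictors removed with a warning.
    encodings_ : dict
        For categorical predictors, the level coded as 1.
    """

    def __init__(
        self,
        predictors=None,
        log_features=DEFAULT_LOG_FEATURES,
        Cs: int = 10,
        cv_folds: int = 10,
        random_state: int = 0,
        max_iter: int = 5000,
        tol: float = 1e-6,
        selection: str = "1se",
    ):
        self.predictors = predictors
        self.log_features = log_features
        self.Cs = Cs
        self.cv_folds = cv_folds
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.selection = selection

    def _design(self, X: pd.DataFrame, fitting: bool) -> pd.DataFrame:
        names = list(
            self.predictors
            if self.predictors is not None
            else [c for c in DEFAULT_PREDICTORS if c in X.columns]
        )
        missing = [c for c in names if c not in X.columns]
        if missing:
            raise ValidationError(f"missing predictor columns: {missing}")
        out = {}
        for name in names:
            col = X[name]
            if col.dtype == object or col.dtype == bool:
                if fitting:
                    levels = sorted(col.astype(str).unique())
                    if len(levels) > 2:
                        raise ValidationError(
                            f"predictor {name!r} has >2 levels: {levels}"
                        )
                    self.encodings_[name] = levels[-1]
                out[name] = (col.astype(str) == self.encodings_[name]).astype(float)
            else:
                values = col.to_numpy(dtype=float)
                if name in self.log_features:
                    values = np.log(np.clip(values, 1e-6, None))
                out[name] = values
        frame = pd.DataFrame(out, index=X.index)
        if fitting:
            self.dropped_ = [
                c for c in frame.columns if frame[c].nunique() <= 1
            ]
            if self.dropped_:
                warnings.warn(
                    f"constant predictors dropped: {self.dropped_}",
                    EgmWarning, stacklevel=3,
                )
            self.predictor_names_ = [
                c for c in frame.columns if c not in self.dropped_
            ]
        return frame[self.predictor_names_]

    def fit(self, X: pd.DataFrame, y, groups=None):
        self.encodings_ = {}
        y = np.asarray(y)
        if set(np.unique(y).tolist()) <= {SUCCESSFUL, UNSUCCESSFUL}:
            self.classes_ = np.array([UNSUCCESSFUL, SUCCESSFUL], dtype=object)
        else:
            self.classes_ = np.unique(y)
        y01 = (y == self.classes_[-1]).astype(int)
        design = self._design(X, fitting=True)

        self.scaler_ = StandardScaler().fit(design.to_numpy())
        Z = self.scaler_.transform(design.to_numpy())

        if groups is not None:
            splitter = StratifiedGroupKFold(
                n_splits=self.cv_folds, shuffle=True,
                random_state=self.random_state,
            )
            folds = list(splitter.split(Z, y01, groups=np.asarray(groups)))
        else:
            splitter = StratifiedKFold(
                n_splits=self.cv_folds, shuffle=True,
                random_state=self.random_state,
            )
            folds = list(splitter.split(Z, y01))

        Cs = (
            np.logspace(-2, 2, self.Cs) if np.isscalar(self.Cs)
            else np.asarray(self.Cs, dtype=float)
        )
        if self.selection not in ("1se", "min"):
            raise ParameterError(
                f"selection must be '1se' or 'min', got {self.selection!r}"
            )
        # per-fold out-of-sample log-likelihood at each penalty strength
        scores = np.empty((len(folds), len(Cs)))
        for i, C in enumerate(Cs):
            for f, (train, test) in enumerate(folds):
                params = self._l1_fit(Z[train], y01[train], C)
                proba = self._sigmoid(Z[test], params)
                scores[f, i] = -log_loss(y01[test], proba, labels=[0, 1])
        mean = scores.mean(axis=0)
        best = int(np.argmax(mean))
        if self.selection == "1se" and len(folds) > 1:
            se = scores[:, best].std(ddof=1) / np.sqrt(len(folds))
            eligible = np.nonzero(mean >= mean[best] - se)[0]
            chosen = int(eligible[np.argmin(Cs[eligible])])
        else:
            chosen = best
        self.C_ = float(Cs[chosen])
        self.cv_scores_ = scores

        self.params_ = self._l1_fit(Z, y01, self.C_)
        self.coef_ = self.params_[1:].copy()
        self.intercept_ = float(self.params_[0])
        if np.abs(self.coef_).max(initial=0.0) > 20.0:
            warnings.warn(
                "very large coefficient: classes may be separable; "
                "the L1 penalty caps but does not remove the divergence",
                EgmWarning, stacklevel=2,
            )
        return self

    @staticmethod
    def _sigmoid(Z: np.ndarray, params: np.ndarray) -> np.ndarray:
        eta = params[0] + Z @ params[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))

    def _l1_fit(self, Z: np.ndarray, y01: np.ndarray, C: float) -> np.ndarray:
        """L1-penalized logistic MLE; the intercept carries no penalty."""
        design = sm.add_constant(Z, has_constant="add")
        alpha = np.r_[0.0, np.full(Z.shape[1], 1.0 / C)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # solver chatter on saturated etas
            result = sm.Logit(y01, design).fit_regularized(
                method="l1", alpha=alpha, disp=0, trim_mode="auto",
                maxiter=self.max_iter, acc=self.tol,
            )
        return np.asarray(result.params, dtype=float)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "params_")
        Z = self.scaler_.transform(self._design(X, fitting=False).to_numpy())
        proba = self._sigmoid(Z, self.params_)
        return np.column_stack([1.0 - proba, proba])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.predict_proba(X)[:, 1]
        return np.where(proba > 0.5, self.classes_[-1], self.classes_[0])
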