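"""Weighted multi-metabolite scores and their internal/external validation.

A score is the weighted sum of (autoscaled) metabolite levels, the weights
being regression coefficients from a penalized discrimination or regression
model.  Internal validity is assessed by leave-one-out cross-validation: each
subject is scored by a model tuned and fitted on the other n-1 subjects, so
the pooled scores are unbiased by that subject's outcome.  Discrimination is
quantified by the AUC (the Mann-Whitney probability of correct ranking) with
a DeLong 95% confidence interval; continuous prediction by the Pearson
correlation with a Fisher-z interval and the adjusted R².  External
validation applies a panel selected on the training cohort to an independent
cohort, either transferring the training weights unchanged or refitting them
by unpenalized regression on the validation data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, LogisticRegression

from .enet import EnetConfig, fit_enet, tune_lambda_cv, with_seed
from .errors import (
    DegenerateInputError,
    FoldDegeneracyError,
    InvalidInputError,
    SchemaError,
)
from .stability import _run_seed

logger = logging.getLogger(__name__)


@dataclass
class ScoreModel:
    """Named feature weights defining a weighted-sum score."""

    feature_names: list[str]
    weights: np.ndarray
    intercept: float = 0.0
    provenance: str = "training"
    family: str = "binomial"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.feature_names) != len(self.weights):
            raise InvalidInputError("feature_names and weights differ in length")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise InvalidInputError("duplicate feature names in score model")
        if np.any(~np.isfinite(self.weights)):
            raise InvalidInputError("weights must be finite")

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "intercept": float(self.intercept),
            "provenance": self.provenance,
            "family": self.family,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreModel":
        return cls(
            feature_names=list(d["feature_names"]),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d.get("intercept", 0.0)),
            provenance=d.get("provenance", "training"),
            family=d.get("family", "binomial"),
        )


@dataclass
class ValidationReport:
    """Validation metrics for one mode (internal LOO, transfer, or refit)."""

    mode: str
    family: str
    n: int
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    pearson_r: float | None = None
    r_ci: tuple[float, float] | None = None
    r2: float | None = None
    adjusted_r2: float | None = None
    excluded_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "family": self.family,
            "n": self.n,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci) if self.auc_ci else None,
            "pearson_r": self.pearson_r,
            "r_ci": list(self.r_ci) if self.r_ci else None,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "excluded_features": self.excluded_features,
        }


def compute_score(X: pd.DataFrame, model: ScoreModel) -> pd.Series:
    """Per-subject weighted-sum score ``intercept + sum_j w_j x_ij``."""
    missing = [f for f in model.feature_names if f not in X.columns]
    if missing:
        raise SchemaError(f"features absent from data: {missing}")
    vals = X[model.feature_names].to_numpy(dtype=float)
    return pd.Series(model.intercept + vals @ model.weights, index=X.index, name="score")


def loo_cv_scores(
    X: pd.DataFrame,
    y,
    config: EnetConfig,
    master_seed: int = 0,
    rescale_per_fold: bool = False,
) -> np.ndarray:
    """Unbiased per-subject scores by leave-one-out cross-validation.

    For each subject the penalty is tuned and the model fitted on the other
    n-1 subjects only (full tuning inside the fold); the held-out subject
    receives the linear predictor of that model.  Fold-degenerate tuning
    draws are retried with fresh entropy as in stability selection.

    By default the feature matrix is used as given (classically scaled once
    on the whole cohort); ``rescale_per_fold=True`` re-estimates centers and
    SDs on each fold's n-1 training subjects and applies them to the held-out
    subject, the leakage-safe variant.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 10:
        raise InvalidInputError("leave-one-out validation requires n >= 10")
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{j}" for j in range(Xv.shape[1])]
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xtr_v = Xv[keep]
        xi = Xv[i]
        if rescale_per_fold:
            centers = Xtr_v.mean(axis=0)
            sds = Xtr_v.std(axis=0, ddof=1)
            if np.any(sds == 0):
                raise InvalidInputError("constant feature inside a LOO fold")
            Xtr_v = (Xtr_v - centers) / sds
            xi = (xi - centers) / sds
        Xtr = pd.DataFrame(Xtr_v, columns=cols)
        ytr = y[keep]
        for redraw in range(6):
            cfg = with_seed(config, _run_seed(master_seed, i, redraw))
            try:
                lam, _ = tune_lambda_cv(Xtr, ytr, cfg, curve_detail=False)
                fit = fit_enet(Xtr, ytr, cfg, lam)
            except FoldDegeneracyError:
                if redraw == 5:
                    raise
                continue
            break
        # Binary scores omit the intercept (AUC-invariant for a fixed model;
        # across LOO folds the intercept tracks the held-out label through the
        # training class balance, an anti-predictive artifact).
        b0 = fit.intercept if config.family == "gaussian" else 0.0
        scores[i] = b0 + xi @ fit.coefficients.to_numpy()
    return scores


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


def auc_with_ci(scores, labels, level: float = 0.95):
    """AUC (Mann-Whitney, ties counted 1/2) with a DeLong confidence interval.

    The variance is the DeLong nonparametric estimate from the per-subject
    placement values; the interval is normal-theory on the AUC scale,
    truncated to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise InvalidInputError("labels must be 0/1")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise InvalidInputError("both classes must be present")
    m, k = len(pos), len(neg)
    # placement values via midranks (ties counted 1/2)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / k          # P(score_neg < pos_i)
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # P(pos > neg_j)
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if k > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / k))
    zq = stats.norm.ppf(0.5 + level / 2)
    lo = max(0.0, auc - zq * se)
    hi = min(1.0, auc + zq * se)
    return auc, lo, hi


def auc_bootstrap_ci(scores, labels, n_boot: int = 2000, seed: int = 0, level: float = 0.95):
    """Percentile bootstrap AUC interval (stratified resampling), seeded."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc, _, _ = auc_with_ci(scores, labels, level)
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=len(pos), replace=True)
        ns = rng.choice(neg, size=len(neg), replace=True)
        s = np.concatenate([ps, ns])
        l = np.concatenate([np.ones(len(ps), int), np.zeros(len(ns), int)])
        boots[b], _, _ = auc_with_ci(s, l, level)
    a = (1 - level) / 2
    return auc, float(np.quantile(boots, a)), float(np.quantile(boots, 1 - a))


def continuous_validation(scores, y, n_model_features: int = 1, level: float = 0.95):
    """Pearson r (Fisher-z CI), R² and adjusted R² of scores against y.

    ``n_model_features`` is the number of predictors behind the score (the
    selected panel size); adjusted R² = 1 - (1 - R²)(n - 1)/(n - p - 1).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise InvalidInputError("need n >= 4 for a correlation interval")
    if np.std(scores) == 0 or np.std(y) == 0:
        raise DegenerateInputError("scores and y must both be non-constant")
    r = float(np.corrcoef(scores, y)[0, 1])
    zq = stats.norm.ppf(0.5 + level / 2)
    z = np.arctanh(min(max(r, -1 + 1e-15), 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    r_ci = (float(np.tanh(z - zq * se)), float(np.tanh(z + zq * se)))
    r2 = r * r
    p = n_model_features
    if n - p - 1 <= 0:
        adj = float("nan")
    else:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return r, r_ci, r2, adj


# --------------------------------------------------------------------------
# external validation and sensitivity analysis
# --------------------------------------------------------------------------


def refit_panel(X: pd.DataFrame, y, panel: list[str], family: str) -> ScoreModel:
    """Unpenalized refit of a fixed panel: logistic or linear regression of
    ``y`` on the panel features; the coefficients become score weights."""
    missing = [f for f in panel if f not in X.columns]
    if missing:
        raise SchemaError(f"panel features absent from data: {missing}")
    Xp = X[panel].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if family == "binomial":
        lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
        lr.fit(Xp, y.astype(int))
        w = lr.coef_.ravel()
        b0 = float(lr.intercept_[0])
    else:
        ols = LinearRegression()
        ols.fit(Xp, y)
        w = ols.coef_
        b0 = float(ols.intercept_)
    return ScoreModel(
        feature_names=list(panel), weights=w, intercept=b0,
        provenance="refit-in-validation", family=family,
    )


def external_validate(
    panel: list[str],
    train_model: ScoreModel | None,
    X_val: pd.DataFrame,
    y_val,
    mode: str = "refit",
    family: str = "binomial",
    n_model_features: int | None = None,
) -> ValidationReport:
    """Validate a trained panel on an independent, separately preprocessed
    cohort.

    ``transfer`` scores the validation subjects with the training weights;
    ``refit`` re-estimates the panel weights by unpenalized regression on the
    validation outcome before scoring.  For the binomial family ``y_val``
    must already be the validation cohort's own median-split labels; for the
    gaussian family it is the (autoscaled) continuous outcome.
    """
    if mode not in ("transfer", "refit"):
        raise InvalidInputError(f"unknown validation mode {mode!r}")
    missing = [f for f in panel if f not in X_val.columns]
    if missing:
        raise SchemaError(f"panel features absent from validation data: {missing}")
    if mode == "transfer":
        if train_model is None:
            raise InvalidInputError("transfer mode requires the training score model")
        model = train_model
    else:
        model = refit_panel(X_val, y_val, panel, family)
    scores = compute_score(X_val, model).to_numpy()
    y_val = np.asarray(y_val, dtype=float)
    report = ValidationReport(
        mode=f"external-{mode}", family=family, n=len(y_val)
    )
    if family == "binomial":
        auc, lo, hi = auc_with_ci(scores, y_val.astype(int))
        report.auc, report.auc_ci = auc, (lo, hi)
    else:
        p = n_model_features if n_model_features is not None else len(panel)
        r, r_ci, r2, adj = continuous_validation(scores, y_val, n_model_features=p)
        report.pearson_r, report.r_ci = r, r_ci
        report.r2, report.adjusted_r2 = r2, adj
    return report


def sensitivity_exclude(features_to_drop: list[str], pipeline, feature_names: list[str]):
    """Re-run a selection+validation pipeline with named features removed.

    ``pipeline`` is a closure taking the list of excluded features and
    returning a report object (or dict of reports); the exclusions are
    recorded on every returned :class:`ValidationReport`.
    """
    missing = [f for f in features_to_drop if f not in feature_names]
    if missing:
        raise SchemaError(f"features to drop not present: {missing}")
    result = pipeline(list(features_to_drop))
    reports = result.values() if isinstance(result, dict) else [result]
    for rep in reports:
        if isinstance(rep, ValidationReport):
            rep.excluded_features = list(features_to_drop)
    return result
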