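"""Preprocessing: missingness filter, random-forest imputation, autoscaling,
and median dichotomization of the outcome.

The steps reproduce the standard metabolomics workflow for penalized
modelling of HOMA-IR: metabolites with at least 20% missing values are
dropped; the remainder are imputed with an iterative random-forest scheme in
the missForest style; features are then autoscaled (centered, unit sample SD);
and the continuous outcome is split at its sample median for the binary
analysis (values at or below the median form the reference class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import (
    DegenerateFeatureError,
    DegenerateOutcomeError,
    EmptyPanelError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

MISSINGNESS_THRESHOLD = 0.20


@dataclass
class PreprocessReport:
    """Record of one preprocessing pass (for provenance and reuse).

    ``scaling_centers``/``scaling_sds`` allow applying the same scaling to new
    subjects; ``mode`` flags whether scaling was estimated on the full dataset
    (the classical whole-cohort convention) or refit per training fold.
    """

    excluded_features: list[str] = field(default_factory=list)
    missing_fractions: dict[str, float] = field(default_factory=dict)
    imputation_iterations: int = 0
    scaling_centers: pd.Series | None = None
    scaling_sds: pd.Series | None = None
    threshold: float = MISSINGNESS_THRESHOLD
    mode: str = "full-dataset-scaling"


def filter_by_missingness(
    metabolites: pd.DataFrame, threshold: float = MISSINGNESS_THRESHOLD
) -> tuple[pd.DataFrame, list[str]]:
    """Retain the columns whose fraction of missing values is strictly below
    ``threshold``; report the excluded names.

    A feature with exactly ``threshold`` missing is excluded (only features
    with *less than* the threshold are imputed downstream).
    """
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError(f"threshold must lie in (0, 1), got {threshold}")
    frac = metabolites.isna().mean(axis=0)
    keep = frac.index[frac < threshold].tolist()
    excluded = frac.index[frac >= threshold].tolist()
    if not keep:
        raise EmptyPanelError(
            f"all {metabolites.shape[1]} metabolites have >= {threshold:.0%} missing"
        )
    return metabolites[keep], excluded


def impute_random_forest(
    matrix: pd.DataFrame,
    max_iter: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
) -> tuple[pd.DataFrame, int]:
    """Iterative random-forest imputation (missForest-style).

    Missing cells are initialized with column means; variables are then
    visited in order of increasing missingness, each regressed on all other
    variables with a random forest fitted on its observed rows and predicted
    on its missing rows.  Iteration stops at the first rise of the normalized
    squared-difference criterion between successive imputations (the previous
    iterate is returned) or at ``max_iter``.  Deterministic given ``seed``.

    Returns the completed matrix and the number of completed iterations.
    Observed cells are never altered.
    """
    if matrix.shape[0] < 10:
        raise InvalidInputError("imputation requires at least 10 rows")
    mask = matrix.isna()
    n_missing_per_col = mask.sum(axis=0)
    fully_missing = n_missing_per_col.index[n_missing_per_col == len(matrix)].tolist()
    if fully_missing:
        raise InvalidInputError(f"columns entirely missing: {fully_missing}")
    if int(n_missing_per_col.sum()) == 0:
        return matrix.copy(), 0

    cols_with_missing = [
        c for c in n_missing_per_col.sort_values(kind="stable").index
        if n_missing_per_col[c] > 0
    ]
    X = matrix.to_numpy(dtype=float).copy()
    col_index = {c: i for i, c in enumerate(matrix.columns)}
    mask_np = mask.to_numpy()
    col_means = np.nanmean(matrix.to_numpy(dtype=float), axis=0)
    for j in range(X.shape[1]):
        X[mask_np[:, j], j] = col_means[j]

    rng = np.random.default_rng(seed)
    prev_imputed = None
    best = X.copy()
    iterations = 0
    prev_criterion = np.inf
    for it in range(max_iter):
        for c in cols_with_missing:
            j = col_index[c]
            obs = ~mask_np[:, j]
            other = np.ones(X.shape[1], dtype=bool)
            other[j] = False
            rf = RandomForestRegressor(
                n_estimators=n_estimators,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(X[obs][:, other], X[obs, j])
            X[~obs, j] = rf.predict(X[~obs][:, other])
        imputed = X[mask_np]
        if prev_imputed is not None:
            criterion = float(
                np.sum((imputed - prev_imputed) ** 2) / max(np.sum(imputed**2), 1e-300)
            )
            if criterion > prev_criterion:
                logger.debug("imputation criterion rose at iteration %d; stopping", it + 1)
                break
            prev_criterion = criterion
        prev_imputed = imputed.copy()
        best = X.copy()
        iterations = it + 1
    out = pd.DataFrame(best, columns=matrix.columns, index=matrix.index)
    # observed cells are restored exactly (guards against dtype round-trips)
    out[~mask] = matrix[~mask]
    return out, iterations


def autoscale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Center each column and scale to unit sample standard deviation (ddof=1).

    Raises :class:`DegenerateFeatureError` naming the first constant column,
    and :class:`InvalidInputError` if any entry is missing.
    """
    if matrix.isna().any().any():
        raise InvalidInputError("autoscale requires a complete matrix; impute first")
    centers = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    bad = sds.index[(sds == 0) | sds.isna()].tolist()
    if bad:
        raise DegenerateFeatureError(f"constant (zero-variance) columns: {bad}")
    return (matrix - centers) / sds, centers, sds


def dichotomize_by_median(values) -> tuple[np.ndarray, float]:
    """Split values at the sample median: label 0 for values at or below the
    median (the reference, lower class), 1 for values strictly above it.

    Returns ``(labels, cutoff)``.  Raises :class:`DegenerateOutcomeError` if a
    class would be empty (e.g. all values identical).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise InvalidInputError("need at least two values to dichotomize")
    if np.any(~np.isfinite(values)):
        raise InvalidInputError("values must be finite")
    cutoff = float(np.median(values))
    labels = (values > cutoff).astype(int)
    if labels.min() == labels.max():
        raise DegenerateOutcomeError(
            f"median split at {cutoff} leaves one class empty"
        )
    return labels, cutoff


def preprocess_cohort(
    metabolites: pd.DataFrame,
    threshold: float = MISSINGNESS_THRESHOLD,
    seed: int = 0,
    max_iter: int = 10,
    n_estimators: int = 100,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Filter, impute and autoscale one cohort's metabolite matrix.

    Row count is preserved; column count shrinks by the number of excluded
    features.  Returns the scaled matrix and a :class:`PreprocessReport`.
    """
    frac = metabolites.isna().mean(axis=0)
    kept, excluded = filter_by_missingness(metabolites, threshold)
    completed, iterations = impute_random_forest(
        kept, max_iter=max_iter, seed=seed, n_estimators=n_estimators
    )
    scaled, centers, sds = autoscale(completed)
    report = PreprocessReport(
        excluded_features=excluded,
        missing_fractions={c: float(frac[c]) for c in metabolites.columns},
        imputation_iterations=iterations,
        scaling_centers=centers,
        scaling_sds=sds,
        threshold=threshold,
    )
    return scaled, report
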