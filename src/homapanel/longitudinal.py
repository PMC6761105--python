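"""Prediction of longitudinal HOMA-IR changes from the baseline score.

The baseline multi-metabolite score is tested against end-of-intervention
HOMA-IR changes under three adjustment models: (i) raw changes, (ii) changes
adjusted for body-weight change, and (iii) changes adjusted for body-weight
change and baseline HOMA-IR.  Adjustment is residualization: ordinary least
squares of the change on an intercept plus the covariates, keeping the
residuals.  Each (residualized) change vector is median-split and the AUC of
the baseline score against those labels computed with its DeLong interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, HomapanelError, InvalidInputError
from .preprocess import dichotomize_by_median
from .scoring import auc_with_ci
from .synthetic import CohortDataset

logger = logging.getLogger(__name__)

ADJUSTMENT_MODES = ("raw", "bw_adjusted", "bw_baseline_adjusted")


@dataclass
class LongitudinalResult:
    """AUC of the baseline score against median-split HOMA-IR changes,
    one entry per adjustment mode."""

    n: int
    modes: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "modes": {
                m: {
                    "auc": v["auc"],
                    "auc_ci": list(v["auc_ci"]),
                    "cutoff": v["cutoff"],
                }
                for m, v in self.modes.items()
            },
            "errors": {m: str(e) for m, e in self.errors.items()},
        }


def compute_changes(cohort: CohortDataset) -> pd.DataFrame:
    """Follow-up minus baseline HOMA-IR and body weight, per subject.

    Subjects missing either timepoint of either variable are dropped (and
    logged).  Returns a DataFrame indexed by subject id with columns
    ``delta_homa``, ``delta_bw``, ``baseline_homa``.
    """
    if cohort.followup is None:
        raise InvalidInputError("cohort has no followup block")
    for key in ("homa_ir", "body_weight"):
        if key not in cohort.followup:
            raise InvalidInputError(f"followup block lacks {key}")
    if cohort.homa_ir is None or cohort.body_weight is None:
        raise InvalidInputError("cohort lacks baseline homa_ir or body_weight")
    delta_homa = cohort.followup["homa_ir"] - cohort.homa_ir
    delta_bw = cohort.followup["body_weight"] - cohort.body_weight
    out = pd.DataFrame(
        {
            "delta_homa": delta_homa,
            "delta_bw": delta_bw,
            "baseline_homa": cohort.homa_ir,
        },
        index=pd.Index(cohort.subject_ids, name="subject_id"),
    )
    complete = out.notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("dropping %d subjects missing a timepoint", dropped)
    return out[complete]


def adjust_changes(delta_homa, covariates=None) -> np.ndarray:
    """Residualize changes on an intercept plus covariates (OLS residuals).

    With no covariates this is simple centering.  Raises
    :class:`DegenerateDesignError` for constant or collinear covariates.
    """
    delta = np.asarray(delta_homa, dtype=float)
    n = len(delta)
    if covariates is None or (hasattr(covariates, "shape") and np.size(covariates) == 0):
        return delta - delta.mean()
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if len(C) != n:
        raise InvalidInputError("covariates and changes differ in length")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateDesignError("constant or collinear covariates")
    coef, *_ = np.linalg.lstsq(design, delta, rcond=None)
    return delta - design @ coef


def longitudinal_auc(baseline_scores, changes: pd.DataFrame) -> LongitudinalResult:
    """AUC of baseline scores against median-split changes for all three
    adjustment modes.

    ``baseline_scores`` must align with ``changes`` (the output of
    :func:`compute_changes`) on the same subjects.  A degenerate median split
    in one mode is recorded as a per-mode error; other modes still report.
    """
    scores = np.asarray(baseline_scores, dtype=float)
    if len(scores) != len(changes):
        raise InvalidInputError("scores and changes must cover the same subjects")
    delta = changes["delta_homa"].to_numpy()
    covs = {
        "raw": None,
        "bw_adjusted": changes[["delta_bw"]].to_numpy(),
        "bw_baseline_adjusted": changes[["delta_bw", "baseline_homa"]].to_numpy(),
    }
    result = LongitudinalResult(n=len(changes))
    for mode in ADJUSTMENT_MODES:
        try:
            adjusted = delta if mode == "raw" else adjust_changes(delta, covs[mode])
            labels, cutoff = dichotomize_by_median(adjusted)
            auc, lo, hi = auc_with_ci(scores, labels)
            result.modes[mode] = {
                "auc": auc,
                "auc_ci": (lo, hi),
                "cutoff": cutoff,
                "labels": labels,
            }
        except HomapanelError as exc:
            logger.warning("mode %s failed: %s", mode, exc)
            result.errors[mode] = exc
    return result
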