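"""Repeated cross-validated selection: the consistency panel.

The selection procedure refits the cross-validation loop many times (100 by
default), each run re-randomizing only the fold assignment, tuning the
penalty at ``lambda.min`` and refitting on the full data.  A metabolite is
"consistently selected" when its coefficient is nonzero in every run; the
per-feature selection count and the median and 2.5th/97.5th percentiles of
its coefficient across runs (zeros from runs where it was not selected
included) summarize the selection landscape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enet import EnetConfig, fit_enet, tune_lambda_cv, with_seed
from .errors import FoldDegeneracyError

logger = logging.getLogger(__name__)


@dataclass
class StabilitySummary:
    """Per-feature selection counts and coefficient summaries over runs.

    ``table`` has one row per feature with columns ``selection_count``,
    ``coefficient_median``, ``ci_low``, ``ci_high`` (2.5th/97.5th percentiles
    across runs, zeros included).  ``consistent_threshold`` defaults to
    ``n_runs`` (selected in every run).
    """

    table: pd.DataFrame
    n_runs: int
    family: str
    consistent_threshold: int | None = None

    def __post_init__(self):
        if self.consistent_threshold is None:
            self.consistent_threshold = self.n_runs

    @property
    def consistent_set(self) -> list[str]:
        t = self.table
        return t.index[t["selection_count"] >= self.consistent_threshold].tolist()

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "family": self.family,
            "consistent_threshold": self.consistent_threshold,
            "features": {
                name: {
                    "selection_count": int(row["selection_count"]),
                    "coefficient_median": float(row["coefficient_median"]),
                    "ci_low": float(row["ci_low"]),
                    "ci_high": float(row["ci_high"]),
                }
                for name, row in self.table.iterrows()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StabilitySummary":
        table = pd.DataFrame.from_dict(d["features"], orient="index")
        return cls(
            table=table,
            n_runs=int(d["n_runs"]),
            family=d["family"],
            consistent_threshold=int(d["consistent_threshold"]),
        )


def _run_seed(master_seed: int, run: int, redraw: int = 0) -> int:
    """Deterministic per-run fold seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(run), int(redraw)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def stability_select(
    X: pd.DataFrame,
    y,
    config: EnetConfig,
    n_runs: int = 100,
    master_seed: int = 0,
    consistent_threshold: int | None = None,
) -> StabilitySummary:
    """Run the repeated-selection procedure.

    Each run derives its fold seed from ``(master_seed, run)``, tunes
    ``lambda.min`` and records the full refit coefficient vector.  A run
    whose fold assignment degenerates (single-class training fold) is
    redrawn with fresh entropy, at most five times.  Deterministic given
    ``master_seed``.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    coefs = []
    for r in range(n_runs):
        for redraw in range(6):
            cfg = with_seed(config, _run_seed(master_seed, r, redraw))
            try:
                lam, _ = tune_lambda_cv(X, y, cfg, curve_detail=False)
                fit = fit_enet(X, y, cfg, lam)
            except FoldDegeneracyError:
                if redraw == 5:
                    raise
                logger.warning("run %d: degenerate folds, redrawing (attempt %d)", r, redraw + 1)
                continue
            break
        coefs.append(fit.coefficients.to_numpy())
        if names is None:
            names = list(fit.coefficients.index)
    C = np.vstack(coefs)  # (n_runs, p)
    table = pd.DataFrame(
        {
            "selection_count": (C != 0).sum(axis=0),
            "coefficient_median": np.median(C, axis=0),
            "ci_low": np.percentile(C, 2.5, axis=0),
            "ci_high": np.percentile(C, 97.5, axis=0),
        },
        index=pd.Index(names, name="feature"),
    )
    return StabilitySummary(
        table=table,
        n_runs=n_runs,
        family=config.family,
        consistent_threshold=consistent_threshold,
    )


def selection_report(summary: StabilitySummary):
    """Ranked selection table plus forest-plot-style figure data.

    The table contains every feature selected at least once, sorted by
    selection count (descending), then absolute median coefficient
    (descending), ties broken alphabetically.  ``figure_data`` lists the
    consistently selected features with their median and percentile interval,
    the layout of a forest plot of the consistent panel.
    """
    t = summary.table
    selected = t[t["selection_count"] >= 1].copy()
    if selected.empty:
        logger.warning("selection summary is empty: no feature was ever selected")
    selected["abs_median"] = selected["coefficient_median"].abs()
    selected = (
        selected.reset_index()
        .sort_values(
            by=["selection_count", "abs_median", "feature"],
            ascending=[False, False, True],
            kind="stable",
        )
        .set_index("feature")
        .drop(columns="abs_median")
    )
    consistent = t.loc[[f for f in summary.consistent_set]]
    consistent = consistent.sort_values("coefficient_median")
    figure_data = {
        "features": consistent.index.tolist(),
        "median": consistent["coefficient_median"].tolist(),
        "ci_low": consistent["ci_low"].tolist(),
        "ci_high": consistent["ci_high"].tolist(),
    }
    return selected, figure_data
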