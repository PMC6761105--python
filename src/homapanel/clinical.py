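"""Cohort-description statistics: Welch's t-test (from raw vectors or
printed summaries), proportion comparison, Friedewald LDL estimation, and
baseline-characteristics tables.

Welch's t-test accommodates unequal variances and sample sizes:

    t  = (m1 - m2) / sqrt(s1²/n1 + s2²/n2)
    df = (s1²/n1 + s2²/n2)² / [ (s1²/n1)²/(n1-1) + (s2²/n2)²/(n2-1) ]

(the Welch-Satterthwaite degrees of freedom), with a two-sided p-value from
the t distribution.  Working from published mean/SD/n triplets makes a
printed comparison table reproducible without subject-level data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTableError,
    InfiniteStatisticError,
    InvalidInputError,
    SchemaError,
)

FRIEDEWALD_TG_LIMIT = 400.0


@dataclass
class GroupSummary:
    """Per-variable summaries for one cohort: (mean, sd, n) for continuous
    variables, (count, n) for categorical ones."""

    continuous: dict = field(default_factory=dict)   # name -> (mean, sd, n)
    categorical: dict = field(default_factory=dict)  # name -> (count, n)


def welch_t_test(mean1, sd1, n1, mean2, sd2, n2):
    """Welch's two-sided t-test from group summaries.

    Returns ``(t, df, p)``.  Zero variance in both groups: equal means give
    ``(0, inf convention) p = 1``; unequal means raise
    :class:`InfiniteStatisticError`.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise InvalidInputError("standard deviations must be non-negative")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    if v1 + v2 == 0.0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise InfiniteStatisticError(
            "zero variance in both groups with unequal means (infinite t)"
        )
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t_test_raw(x1, x2):
    """Welch's t-test on raw vectors (summaries computed internally, so the
    result matches :func:`welch_t_test` on those summaries exactly)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return welch_t_test(
        x1.mean(), x1.std(ddof=1), len(x1),
        x2.mean(), x2.std(ddof=1), len(x2),
    )


def proportion_test(count1, n1, count2, n2, method: str = "chi2") -> float:
    """Two-sided comparison of two proportions via the 2x2 table.

    ``chi2`` applies the continuity-corrected chi-square test; ``fisher`` the
    exact test.  Raises :class:`DegenerateTableError` on a zero margin.
    """
    if count1 > n1 or count2 > n2 or min(count1, count2) < 0:
        raise InvalidInputError("counts must lie in [0, n]")
    table = np.array([[count1, n1 - count1], [count2, n2 - count2]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTableError(f"zero margin in table {table.tolist()}")
    if method == "chi2":
        _, p, _, _ = stats.chi2_contingency(table, correction=True)
    elif method == "fisher":
        _, p = stats.fisher_exact(table, alternative="two-sided")
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    return float(p)


def friedewald_ldl(tc, hdl, tg):
    """Friedewald LDL-C estimate ``tc - hdl - tg/5`` (all mg/dL).

    Only valid for TG < 400 mg/dL; raises :class:`NotEstimableError`
    otherwise.  Vectorized.
    """
    from .errors import NotEstimableError

    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if np.any(tg >= FRIEDEWALD_TG_LIMIT):
        raise NotEstimableError(
            f"Friedewald formula not applicable at TG >= {FRIEDEWALD_TG_LIMIT:.0f} mg/dL"
        )
    out = tc - hdl - tg / 5.0
    return float(out) if out.ndim == 0 else out

#: Default table rows: (variable, kind) with kind one of
#: continuous | categorical | median_iqr.
DEFAULT_TABLE_VARIABLES = (
    ("age", "continuous"),
    ("sex", "categorical"),
    ("body_weight", "continuous"),
    ("glucose", "continuous"),
    ("insulin", "continuous"),
    ("homa_ir", "continuous"),
    ("homa_ir", "median_iqr"),
    ("tc", "continuous"),
    ("hdl", "continuous"),
    ("ldl", "continuous"),
    ("tg", "continuous"),
)


def _summaries(source, variable: str, kind: str):
    """(mean, sd, n) or (count, n) for one variable from a cohort or a
    GroupSummary."""
    if isinstance(source, GroupSummary):
        store = source.categorical if kind == "categorical" else source.continuous
        if variable not in store:
            raise SchemaError(f"variable {variable!r} absent from summary")
        return store[variable], None
    values = getattr(source, variable, None)
    if values is None:
        raise SchemaError(f"variable {variable!r} absent from cohort")
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if kind == "categorical":
        return (int(values.sum()), len(values)), values
    return (float(values.mean()), float(values.std(ddof=1)), len(values)), values


def cohort_table(
    cohort_a,
    cohort_b,
    variables=DEFAULT_TABLE_VARIABLES,
    categorical_method: str = "chi2",
) -> pd.DataFrame:
    """Baseline-characteristics comparison of two cohorts.

    Continuous rows report mean ± SD per cohort and the Welch p-value;
    categorical rows report % (N) and a proportion-test p-value; rows flagged
    ``median_iqr`` report median [Q1-Q3] (linear-interpolation quantiles)
    without a test.  Accepts :class:`CohortDataset` or
    :class:`GroupSummary` inputs (summary input supports continuous and
    categorical rows only).
    """
    rows = []
    for variable, kind in variables:
        sa, raw_a = _summaries(cohort_a, variable, "categorical" if kind == "categorical" else "continuous")
        sb, raw_b = _summaries(cohort_b, variable, "categorical" if kind == "categorical" else "continuous")
        if kind == "continuous":
            t, df, p = welch_t_test(*sa, *sb)
            fmt_a = f"{sa[0]:.2f} ± {sa[1]:.2f}"
            fmt_b = f"{sb[0]:.2f} ± {sb[1]:.2f}"
        elif kind == "categorical":
            p = proportion_test(sa[0], sa[1], sb[0], sb[1], method=categorical_method)
            fmt_a = f"{100 * sa[0] / sa[1]:.2f} ({sa[0]})"
            fmt_b = f"{100 * sb[0] / sb[1]:.2f} ({sb[0]})"
        elif kind == "median_iqr":
            if raw_a is None or raw_b is None:
                raise InvalidInputError("median [IQR] rows require raw cohort data")
            qa = np.quantile(raw_a, [0.5, 0.25, 0.75])
            qb = np.quantile(raw_b, [0.5, 0.25, 0.75])
            fmt_a = f"{qa[0]:.2f} [{qa[1]:.2f}-{qa[2]:.2f}]"
            fmt_b = f"{qb[0]:.2f} [{qb[1]:.2f}-{qb[2]:.2f}]"
            p = np.nan
        else:
            raise InvalidInputError(f"unknown row kind {kind!r}")
        label = f"{variable} (median [IQR])" if kind == "median_iqr" else variable
        rows.append({"variable": label, "cohort_a": fmt_a, "cohort_b": fmt_b, "p_value": p})
    return pd.DataFrame(rows).set_index("variable")
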