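"""Responder / non-responder fold changes and the two t-test comparisons.

Fold change per analyte is ``log2(mean MFR of responders / mean MFR of
non-responders)`` on raw (untransformed) MFR means, so a positive value
means higher expression in responders.  Baseline group differences use an
unpaired t-test (Welch by default), pre/post differences within a group use
a paired t-test.  No multiple-comparison adjustment is applied anywhere in
this module; adjustment is an opt-in elsewhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ExpressionTable

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTestResult",
    "fold_change",
    "unpaired_ttest",
    "paired_ttest",
    "unpaired_ttests",
    "paired_ttests",
]


def fold_change(
    table: ExpressionTable,
    cell_type: str,
    timepoint: str = "baseline",
    mean: str = "arithmetic",
) -> pd.DataFrame:
    """Per-analyte fold change between responders and non-responders.

    Returns a frame indexed by analyte with columns ``n_resp, n_nonresp,
    mean_resp, mean_nonresp, fc``.  ``mean`` may be "arithmetic" (default)
    or "geometric".  Relabeling the two groups negates every fold change,
    and scaling all MFR values by a positive constant leaves it unchanged.
    """
    if mean not in ("arithmetic", "geometric"):
        raise ValidationError(f"unknown mean kind {mean!r}")
    resp = table.wide(cell_type, "responder", timepoint)
    nonresp = table.wide(cell_type, "nonresponder", timepoint)
    missing = (set(resp.columns) ^ set(nonresp.columns))
    if missing:
        raise ValidationError(
            f"analytes missing in one group at ({cell_type}, {timepoint}): {sorted(missing)}"
        )
    analytes = list(resp.columns)
    nonresp = nonresp[analytes]
    if mean == "arithmetic":
        m_r, m_n = resp.mean(axis=0), nonresp.mean(axis=0)
    else:
        m_r = np.exp(np.log(resp).mean(axis=0))
        m_n = np.exp(np.log(nonresp).mean(axis=0))
    out = pd.DataFrame(
        {
            "n_resp": len(resp),
            "n_nonresp": len(nonresp),
            "mean_resp": m_r,
            "mean_nonresp": m_n,
            "fc": np.log2(m_r / m_n),
        },
        index=pd.Index(analytes, name="analyte"),
    )
    return out


@dataclass(frozen=True)
class GroupTestResult:
    """One t-test comparison for a (cell type, analyte) pair."""

    cell_type: str
    analyte: str
    kind: str  # "unpaired-baseline" or "paired-pre-post"
    t: float
    df: float
    p: float
    n1: int
    n2: int
    degenerate: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p-value {self.p} outside [0, 1]")


def _values(table: ExpressionTable, cell_type: str, analyte: str,
            group: str, timepoint: str) -> pd.Series:
    df = table.data
    mask = (
        (df["cell_type"] == cell_type)
        & (df["analyte"] == analyte)
        & (df["group"] == group)
        & (df["timepoint"] == timepoint)
    )
    sub = df.loc[mask].set_index("subject_id")["mfr"]
    return sub.sort_index()


def unpaired_ttest(
    table: ExpressionTable,
    cell_type: str,
    analyte: str,
    timepoint: str = "baseline",
    equal_var: bool = False,
) -> GroupTestResult:
    """Two-sided unpaired t-test of responders vs non-responders.

    Welch (unequal variances) by default; set ``equal_var=True`` for the
    pooled-variance form.  Zero-variance strata are flagged rather than
    raised so whole-panel sweeps never abort: equal means give p = 1 by
    convention, unequal means give the p -> 0 limit with a warning.
    """
    x = _values(table, cell_type, analyte, "responder", timepoint).to_numpy()
    y = _values(table, cell_type, analyte, "nonresponder", timepoint).to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ValidationError(
            f"unpaired t-test needs >= 2 subjects per group for {analyte} "
            f"({cell_type}, {timepoint}); got {len(x)}/{len(y)}"
        )
    kind = f"unpaired-{timepoint}"
    df_pooled = float(len(x) + len(y) - 2)
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if np.mean(x) == np.mean(y):
            return GroupTestResult(cell_type, analyte, kind, 0.0, df_pooled, 1.0,
                                   len(x), len(y), degenerate=True,
                                   note="zero variance in both groups, equal means")
        warnings.warn(
            f"{analyte}: zero variance with unequal means; p reported as 0-limit",
            stacklevel=2,
        )
        t = np.inf if np.mean(x) > np.mean(y) else -np.inf
        return GroupTestResult(cell_type, analyte, kind, float(t), df_pooled, 0.0,
                               len(x), len(y), degenerate=True,
                               note="zero variance with unequal means")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return GroupTestResult(cell_type, analyte, kind, float(res.statistic),
                           float(res.df), float(res.pvalue), len(x), len(y))


def paired_ttest(
    table: ExpressionTable,
    cell_type: str,
    analyte: str,
    group: str = "responder",
) -> GroupTestResult:
    """Two-sided paired t-test on post - baseline differences within *group*.

    Subjects lacking either timepoint are excluded with a logged count.
    """
    pre = _values(table, cell_type, analyte, group, "baseline")
    post = _values(table, cell_type, analyte, group, "post")
    shared = sorted(set(pre.index) & set(post.index))
    dropped = len(set(pre.index) | set(post.index)) - len(shared)
    if dropped:
        logger.info(
            "paired t-test %s/%s/%s: excluded %d subject(s) lacking a timepoint",
            cell_type, analyte, group, dropped,
        )
    if len(shared) < 2:
        raise ValidationError(
            f"paired t-test needs >= 2 complete pairs for {analyte} ({cell_type}, {group}); "
            f"got {len(shared)}"
        )
    d = post.loc[shared].to_numpy() - pre.loc[shared].to_numpy()
    n = len(d)
    kind = "paired-pre-post"
    if np.var(d, ddof=1) == 0.0:
        if np.all(d == 0.0):
            return GroupTestResult(cell_type, analyte, kind, 0.0, float(n - 1), 1.0,
                                   n, n, degenerate=True, note="all differences zero")
        warnings.warn(
            f"{analyte}: constant nonzero difference; p reported as 0-limit",
            stacklevel=2,
        )
        t = np.inf if d[0] > 0 else -np.inf
        return GroupTestResult(cell_type, analyte, kind, float(t), float(n - 1), 0.0,
                               n, n, degenerate=True, note="constant nonzero difference")
    res = stats.ttest_rel(post.loc[shared].to_numpy(), pre.loc[shared].to_numpy())
    return GroupTestResult(cell_type, analyte, kind, float(res.statistic),
                           float(n - 1), float(res.pvalue), n, n)


def _results_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_type": r.cell_type, "analyte": r.analyte, "kind": r.kind,
                "t": r.t, "df": r.df, "p": r.p, "n1": r.n1, "n2": r.n2,
                "degenerate": r.degenerate, "note": r.note,
            }
            for r in results
        ]
    )


def unpaired_ttests(
    table: ExpressionTable,
    timepoint: str = "baseline",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Unpaired t-tests for every (cell type, analyte)."""
    results = [
        unpaired_ttest(table, ct, a, timepoint=timepoint, equal_var=equal_var)
        for ct in table.cell_types()
        for a in table.analytes()
    ]
    return _results_frame(results)


def paired_ttests(table: ExpressionTable, group: str = "responder") -> pd.DataFrame:
    """Paired t-tests for every (cell type, analyte) within *group*."""
    results = [
        paired_ttest(table, ct, a, group=group)
        for ct in table.cell_types()
        for a in table.analytes()
    ]
    return _results_frame(results)
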