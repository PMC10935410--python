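"""Pairwise correlation grids and anchor-analyte before/after profiles.

The correlation between two analytes is the ordinary least-squares (simple
linear regression) fit, reported as R²; its two-sided p-value comes from
the exact equivalence with the Pearson correlation test,

    t = r * sqrt((n - 2) / (1 - r²)),  df = n - 2.

Significance classes follow the grid-legend convention: ``strong`` for
p < 0.01, ``moderate`` for 0.01 <= p <= 0.05, ``ns`` for p > 0.05 and
``self`` on the diagonal (r = 1).  Correlations are computed on raw MFR by
default; a log-transform switch exists for sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ExpressionTable

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_STRONG",
    "CLASS_MODERATE",
    "CLASS_NS",
    "CLASS_SELF",
    "CorrelationGrid",
    "AnchorProfile",
    "GridComparison",
    "classify_significance",
    "pairwise_correlation",
    "count_significant",
    "anchor_profile",
    "compare_grids",
]

CLASS_STRONG = "strong"
CLASS_MODERATE = "moderate"
CLASS_NS = "ns"
CLASS_SELF = "self"


def classify_significance(p: float) -> str:
    """Map a p-value to its grid class.

    strong  <=> p < 0.01
    moderate <=> 0.01 <= p <= 0.05
    ns      <=> p > 0.05

    The p = 0.01 boundary falls in the moderate class because the strong
    threshold is a strict inequality.
    """
    if math.isnan(p) or not (0.0 <= p <= 1.0):
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if p < 0.01:
        return CLASS_STRONG
    if p <= 0.05:
        return CLASS_MODERATE
    return CLASS_NS


def _pearson_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r and two-sided p for the columns of X (n x m).

    Columns with zero variance yield NaN r and NaN p (flagged, treated as
    non-significant downstream).
    """
    n, m = X.shape
    Xc = X - X.mean(axis=0)
    ss = np.einsum("ij,ij->j", Xc, Xc)
    denom = np.sqrt(np.outer(ss, ss))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Xc) / denom
    constant = ss == 0.0
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    return r, p


@dataclass(frozen=True)
class CorrelationGrid:
    """Symmetric r / p / class matrices for one (cell type, group, timepoint) stratum."""

    cell_type: str
    group: str
    timepoint: str
    analytes: tuple[str, ...]
    n: int
    r: np.ndarray
    p: np.ndarray

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    def classes(self) -> np.ndarray:
        m = len(self.analytes)
        out = np.empty((m, m), dtype=object)
        for i in range(m):
            for j in range(m):
                if i == j:
                    out[i, j] = CLASS_SELF
                elif np.isnan(self.p[i, j]):
                    out[i, j] = CLASS_NS
                else:
                    out[i, j] = classify_significance(float(self.p[i, j]))
        return out

    def _significant_mask(self, level: float) -> np.ndarray:
        p = self.p
        with np.errstate(invalid="ignore"):
            # strict inequality at the 0.01 (strong) level, inclusive at 0.05
            mask = (p < level) if level == 0.01 else (p <= level)
        mask &= ~np.isnan(p)
        np.fill_diagonal(mask, False)
        return mask

    def count_significant(self, level: float = 0.05) -> int:
        """Number of unordered off-diagonal pairs significant at *level*."""
        mask = self._significant_mask(level)
        return int(np.triu(mask, k=1).sum())

    def significant_pairs(self, level: float = 0.05) -> frozenset[tuple[str, str]]:
        mask = self._significant_mask(level)
        out = set()
        for i, j in zip(*np.nonzero(np.triu(mask, k=1))):
            a, b = self.analytes[i], self.analytes[j]
            out.add(tuple(sorted((a, b))))
        return frozenset(out)

    def to_frame(self, which: str = "r2") -> pd.DataFrame:
        data = {"r": self.r, "r2": self.r2, "p": self.p, "class": self.classes()}[which]
        return pd.DataFrame(data, index=list(self.analytes), columns=list(self.analytes))


def pairwise_correlation(
    table: ExpressionTable,
    cell_type: str,
    group: str,
    timepoint: str = "baseline",
    analytes: tuple[str, ...] | None = None,
    subjects: tuple[str, ...] | None = None,
    log_transform: bool = False,
) -> CorrelationGrid:
    """Correlation grid for one stratum (requires at least 3 subjects)."""
    wide = table.wide(cell_type, group, timepoint, subjects=subjects)
    if analytes is None:
        analytes = tuple(sorted(wide.columns))
    else:
        missing = set(analytes) - set(wide.columns)
        if missing:
            raise ValidationError(f"analytes absent from stratum: {sorted(missing)}")
    wide = wide[list(analytes)]
    n = len(wide)
    if n < 3:
        raise ValidationError(
            f"correlation needs >= 3 subjects in ({cell_type}, {group}, {timepoint}); got {n}"
        )
    X = wide.to_numpy(dtype=float)
    if log_transform:
        X = np.log(X)
    if (X.std(axis=0) == 0.0).any():
        const = [a for a, s in zip(analytes, X.std(axis=0)) if s == 0.0]
        logger.warning("constant analytes in stratum (r undefined, class ns): %s", const)
    r, p = _pearson_matrix(X)
    return CorrelationGrid(cell_type, group, timepoint, tuple(analytes), n, r, p)


def count_significant(grid: CorrelationGrid, level: float = 0.05) -> int:
    """Module-level convenience mirroring :meth:`CorrelationGrid.count_significant`."""
    return grid.count_significant(level)


@dataclass(frozen=True)
class AnchorProfile:
    """R² and p of one anchor analyte versus every other analyte, before and after.

    Both timepoints are restricted to the paired-subject subset so the
    before/after comparison is not confounded by a change of sample.
    """

    anchor: str
    cell_type: str
    group: str
    analytes: tuple[str, ...]  # the other analytes (anchor excluded)
    n_baseline: int
    n_post: int
    r2_baseline: np.ndarray
    p_baseline: np.ndarray
    r2_post: np.ndarray
    p_post: np.ndarray

    def count_significant(self, level: float = 0.05, timepoint: str = "baseline") -> int:
        p = {"baseline": self.p_baseline, "post": self.p_post}[timepoint]
        with np.errstate(invalid="ignore"):
            mask = (p < level) if level == 0.01 else (p <= level)
        return int((mask & ~np.isnan(p)).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "analyte": list(self.analytes),
                "r2_baseline": self.r2_baseline,
                "p_baseline": self.p_baseline,
                "r2_post": self.r2_post,
                "p_post": self.p_post,
            }
        )


def anchor_profile(
    table: ExpressionTable,
    anchor: str,
    cell_type: str,
    group: str = "responder",
    analytes: tuple[str, ...] | None = None,
    log_transform: bool = False,
) -> AnchorProfile:
    """Before/after correlation profile of *anchor* against all other analytes."""
    paired = table.paired_subjects(group)
    if len(paired) < 3:
        raise ValidationError(
            f"anchor profile needs >= 3 paired subjects in {group}; got {len(paired)}"
        )
    grids = {
        tp: pairwise_correlation(
            table, cell_type, group, tp,
            analytes=analytes, subjects=paired, log_transform=log_transform,
        )
        for tp in ("baseline", "post")
    }
    base = grids["baseline"]
    if anchor not in base.analytes:
        raise ValidationError(f"anchor {anchor!r} not in panel {base.analytes}")
    idx = base.analytes.index(anchor)
    others = [i for i in range(len(base.analytes)) if i != idx]
    names = tuple(base.analytes[i] for i in others)
    post = grids["post"]
    return AnchorProfile(
        anchor=anchor,
        cell_type=cell_type,
        group=group,
        analytes=names,
        n_baseline=base.n,
        n_post=post.n,
        r2_baseline=base.r2[idx, others],
        p_baseline=base.p[idx, others],
        r2_post=post.r2[idx, others],
        p_post=post.p[idx, others],
    )


@dataclass(frozen=True)
class GridComparison:
    """Significant-pair counts of two grids and their overlap."""

    counts_a: dict[float, int]
    counts_b: dict[float, int]
    difference: dict[float, int]  # counts_a - counts_b per level
    shared_pairs: frozenset[tuple[str, str]]  # significant (p <= 0.05) in both


def compare_grids(
    a: CorrelationGrid,
    b: CorrelationGrid,
    levels: tuple[float, ...] = (0.05, 0.01),
) -> GridComparison:
    """Compare two grids over the same analyte panel."""
    if a.analytes != b.analytes:
        raise ValidationError("grids have different analyte panels")
    counts_a = {lv: a.count_significant(lv) for lv in levels}
    counts_b = {lv: b.count_significant(lv) for lv in levels}
    diff = {lv: counts_a[lv] - counts_b[lv] for lv in levels}
    shared = a.significant_pairs(0.05) & b.significant_pairs(0.05)
    return GridComparison(counts_a, counts_b, diff, shared)
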