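"""Hypergeometric pathway over-representation of a module, with optional
Benjamini-Hochberg adjustment.

For a universe of N genes containing a pathway of size K, a module of size n
drawn without replacement would overlap the pathway in X ~ Hypergeometric(N,
K, n) genes; the enrichment p-value is the upper tail P(X >= k) at the
observed overlap k.  Adjustment is off by default (the upstream analyses are
explicitly unadjusted) and available as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._symbols import normalize_symbol
from .errors import ValidationError
from .io import GeneSetCollection

__all__ = [
    "UNIVERSE_RULES",
    "EnrichmentRow",
    "hypergeometric_test",
    "build_universe",
    "enrich_all",
    "bh_adjust",
    "rows_to_frame",
]

UNIVERSE_RULES = ("graph-nodes", "graph-geneset-intersection", "explicit-list")


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when a module of size *n* is drawn uniformly without
    replacement from a universe of size *N* containing a pathway of size *K*.
    Computed via the log-gamma based survival function (numerically stable
    for small tail probabilities).
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer; got {v}")
    if K > N or n > N:
        raise ValidationError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValidationError(f"overlap k={k} exceeds min(K={K}, n={n})")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def build_universe(
    rule: str,
    graph=None,
    gene_sets: GeneSetCollection | None = None,
    explicit=None,
) -> frozenset[str]:
    """Resolve the enrichment universe.

    * ``graph-nodes``: all host-graph nodes.
    * ``graph-geneset-intersection`` (default downstream): host-graph nodes
      that appear in at least one gene set — genes the analysis could never
      have selected are not counted.
    * ``explicit-list``: a caller-provided gene list.
    """
    if rule not in UNIVERSE_RULES:
        raise ValidationError(f"unknown universe rule {rule!r}; choose from {UNIVERSE_RULES}")
    if rule == "graph-nodes":
        if graph is None:
            raise ValidationError("graph required for rule 'graph-nodes'")
        return frozenset(normalize_symbol(n) for n in graph.nodes)
    if rule == "graph-geneset-intersection":
        if graph is None or gene_sets is None:
            raise ValidationError("graph and gene_sets required for the intersection rule")
        nodes = frozenset(normalize_symbol(n) for n in graph.nodes)
        return nodes & gene_sets.universe()
    if explicit is None:
        raise ValidationError("explicit gene list required for rule 'explicit-list'")
    return frozenset(normalize_symbol(g) for g in explicit)


@dataclass(frozen=True)
class EnrichmentRow:
    """One pathway's overlap with the module and its hypergeometric p."""

    pathway: str
    N: int  # universe size
    K: int  # pathway genes in universe
    n: int  # module genes in universe
    k: int  # overlap
    overlap: tuple[str, ...]
    p: float
    p_adj: float | None = None


def enrich_all(
    module,
    gene_sets: GeneSetCollection,
    universe,
    adjust: bool = False,
) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of *module* against every gene set.

    Module and pathways are trimmed to the universe; pathways with no gene in
    the universe are dropped.  Rows are sorted by ascending p then pathway
    name, with sorted overlap gene lists, so the output is invariant to the
    input ordering of pathways and module genes.
    """
    if len(gene_sets) == 0:
        raise ValidationError("empty gene-set collection")
    universe = frozenset(normalize_symbol(g) for g in universe)
    module = {normalize_symbol(g) for g in module} & universe
    if not module:
        raise ValidationError("module is empty after trimming to the universe")
    N, n = len(universe), len(module)
    rows = []
    for name in gene_sets.names():
        members = gene_sets[name] & universe
        if not members:
            continue
        overlap = tuple(sorted(module & members))
        rows.append(
            EnrichmentRow(
                pathway=name,
                N=N,
                K=len(members),
                n=n,
                k=len(overlap),
                overlap=overlap,
                p=hypergeometric_test(len(overlap), len(members), n, N),
            )
        )
    rows.sort(key=lambda r: (r.p, r.pathway))
    if adjust and rows:
        adjusted = bh_adjust([r.p for r in rows])
        rows = [
            EnrichmentRow(r.pathway, r.N, r.K, r.n, r.k, r.overlap, r.p, float(q))
            for r, q in zip(rows, adjusted)
        ]
    return rows


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rows_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway, "N": r.N, "K": r.K, "n": r.n, "k": r.k,
                "overlap_genes": ";".join(r.overlap), "p": r.p,
                "p_adj": r.p_adj if r.p_adj is not None else "",
            }
            for r in rows
        ]
    )
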