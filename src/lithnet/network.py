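"""Analyte-to-gene mapping, shortest-path network induction, random-walk-with-
restart propagation, module identification and pathway subnetworks.

The measured analytes collapse to gene symbols (several phospho-forms map to
one gene), the mapped genes seed the analysis, and the induced network is the
seed set plus every host-graph node lying on any shortest path between a seed
pair ("connector" nodes, unmeasured proteins).  Propagation iterates

    s <- alpha * e + (1 - alpha) * W s

with W the column-normalized adjacency and e uniform over the seeds; the
fixed point scores each node's network proximity to the seeds.  The module is
the largest connected component of the top-k scoring nodes and is the unit
passed to pathway enrichment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._symbols import normalize_symbol
from .errors import FormatError, ValidationError
from .panel import DEFAULT_PANEL, AnalytePanel

logger = logging.getLogger(__name__)

__all__ = [
    "MappingRow",
    "GeneMapping",
    "default_mapping",
    "read_mapping",
    "write_mapping",
    "map_analytes_to_genes",
    "InducedNetwork",
    "PropagationResult",
    "shortest_path_induction",
    "random_walk_restart",
    "identify_module",
    "annotate_with_fc",
    "extract_pathway_subnetwork",
]


# ---------------------------------------------------------------------------
# analyte -> gene mapping


@dataclass(frozen=True)
class MappingRow:
    analyte: str
    gene: str  # normalized symbol
    in_network: bool  # False for analytes excluded from the network gene set


@dataclass(frozen=True)
class GeneMapping:
    """Total mapping from panel analytes to gene symbols.

    Several analytes may share one gene (a collapse group, e.g. the three
    GSK3 phospho-forms); analytes flagged ``in_network=False`` carry a gene
    symbol but are excluded from the seed set.
    """

    rows: tuple[MappingRow, ...]
    _by_analyte: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by = {}
        for row in self.rows:
            if row.analyte in by:
                raise ValidationError(f"duplicate mapping for analyte {row.analyte!r}")
            by[row.analyte] = row
        object.__setattr__(self, "_by_analyte", by)

    def gene_for(self, analyte: str) -> str:
        try:
            return self._by_analyte[analyte].gene
        except KeyError:
            raise ValidationError(f"analyte {analyte!r} absent from mapping") from None

    def row_for(self, analyte: str) -> MappingRow:
        try:
            return self._by_analyte[analyte]
        except KeyError:
            raise ValidationError(f"analyte {analyte!r} absent from mapping") from None

    def network_genes(self) -> tuple[str, ...]:
        return tuple(sorted({r.gene for r in self.rows if r.in_network}))

    def excluded_analytes(self) -> tuple[str, ...]:
        return tuple(r.analyte for r in self.rows if not r.in_network)

    def analytes_for(self, gene: str, in_network_only: bool = True) -> tuple[str, ...]:
        return tuple(
            r.analyte
            for r in self.rows
            if r.gene == gene and (r.in_network or not in_network_only)
        )


# Default mapping of the 28-analyte panel.  The "figure" convention follows
# the symbols used in the study's network figure verbatim (NFKB1 for the p65
# subunit, NOS1 for iNOS, PRKCA for PKA C-alpha); the "hgnc" alternative uses
# the conventional HGNC assignments for those three (RELA, NOS2, PRKACA).
# PDEB4 and XBP1 carry symbols but are excluded from the network gene set.
_FIGURE_GENES = {
    "NLRP3": "NLRP3",
    "PDEB4": "PDE4B",
    "BAX": "BAX",
    "phospho-Fyn/phospho-Yes": "FYN",
    "HMGB1": "HMGB1",
    "BCL-2 A1": "BCL2A1",
    "BDNF": "BDNF",
    "GSK3β": "GSK3B",
    "XBP1": "XBP1",
    "MARCKS": "MARCKS",
    "phospho-GSK3β": "GSK3B",
    "phospho-GSK3α/β": "GSK3B",
    "Fyn": "FYN",
    "Timeless": "TIMELESS",
    "PGM1": "PGM1",
    "phospho-NFkB-P65": "NFKB1",
    "CALM1": "CALM1",
    "IRS2": "IRS2",
    "phospho-CREB": "CREB1",
    "PPAR-γ": "PPARG",
    "TNFAIP3": "TNFAIP3",
    "TPH1": "TPH1",
    "PKC-θ": "PRKCQ",
    "BCL-2": "BCL2",
    "iNOS": "NOS1",
    "NR3C1": "NR3C1",
    "mTor": "MTOR",
    "PKA C-α": "PRKCA",
}
_HGNC_OVERRIDES = {"phospho-NFkB-P65": "RELA", "iNOS": "NOS2", "PKA C-α": "PRKACA"}
_EXCLUDED = ("PDEB4", "XBP1")


def default_mapping(panel: AnalytePanel = DEFAULT_PANEL, convention: str = "figure") -> GeneMapping:
    """The shipped analyte-to-gene mapping for the 28-analyte panel."""
    if convention not in ("figure", "hgnc"):
        raise ValidationError(f"unknown mapping convention {convention!r}")
    genes = dict(_FIGURE_GENES)
    if convention == "hgnc":
        genes.update(_HGNC_OVERRIDES)
    rows = []
    for analyte in panel:
        if analyte not in genes:
            raise ValidationError(f"no default mapping for analyte {analyte!r}")
        rows.append(MappingRow(analyte, normalize_symbol(genes[analyte]),
                               in_network=analyte not in _EXCLUDED))
    return GeneMapping(rows=tuple(rows))


def identity_mapping(analytes) -> GeneMapping:
    """One gene per analyte (normalized analyte name), all in-network.

    Used for ad-hoc panels without a curated mapping table.
    """
    return GeneMapping(
        rows=tuple(MappingRow(a, normalize_symbol(a), True) for a in analytes)
    )


def read_mapping(path: str | Path) -> GeneMapping:
    """Read a mapping TSV with columns analyte, gene, collapse_group, in_network."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    needed = {"analyte", "gene", "in_network"}
    if not needed <= set(df.columns):
        raise FormatError(f"mapping file must have columns {sorted(needed)}")
    rows = tuple(
        MappingRow(
            analyte=str(rec.analyte),
            gene=normalize_symbol(str(rec.gene)),
            in_network=str(rec.in_network).strip().lower() in ("true", "1", "yes"),
        )
        for rec in df.itertuples()
    )
    return GeneMapping(rows=rows)


def write_mapping(mapping: GeneMapping, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "analyte": r.analyte,
                "gene": r.gene,
                "collapse_group": r.gene,
                "in_network": str(r.in_network).lower(),
            }
            for r in mapping.rows
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def map_analytes_to_genes(
    panel: AnalytePanel, mapping: GeneMapping
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Collapse the panel to unique network gene symbols.

    Returns ``(genes, excluded_analytes)`` where *genes* is the sorted tuple
    of unique in-network symbols and *excluded_analytes* lists panel analytes
    flagged out of the network.  Raises if any panel analyte is unmapped.
    """
    genes: set[str] = set()
    excluded: list[str] = []
    for analyte in panel:
        row = mapping.row_for(analyte)
        if row.in_network:
            genes.add(row.gene)
        else:
            excluded.append(analyte)
    return tuple(sorted(genes)), tuple(excluded)


# ---------------------------------------------------------------------------
# induced networks


@dataclass(frozen=True)
class InducedNetwork:
    """A seed-induced subgraph with node roles and optional annotations.

    ``roles`` maps each node to "seed" (measured) or "connector" (unmeasured,
    on a shortest path between seeds); ``fc`` carries the fold-change
    annotation (None for connectors and unannotated networks); ``scores``
    carries propagation scores when attached.
    """

    graph: nx.Graph
    roles: dict[str, str]
    fc: dict[str, float | None] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)
    dropped_seeds: tuple[str, ...] = ()
    skipped_pairs: int = 0

    def seeds(self) -> tuple[str, ...]:
        return tuple(sorted(n for n, role in self.roles.items() if role == "seed"))

    def connectors(self) -> tuple[str, ...]:
        return tuple(sorted(n for n, role in self.roles.items() if role == "connector"))

    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    def to_graph(self) -> nx.Graph:
        """Annotated copy: node attributes role, fc (None if unmeasured), rwr_score."""
        g = nx.Graph()
        for node in sorted(self.graph.nodes):
            g.add_node(
                node,
                role=self.roles[node],
                fc=self.fc.get(node),
                rwr_score=self.scores.get(node),
            )
        g.add_edges_from(self.graph.edges)
        return g

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "node": n,
                "role": self.roles[n],
                "fc": self.fc.get(n),
                "rwr_score": self.scores.get(n),
                "degree": self.graph.degree[n],
            }
            for n in sorted(self.graph.nodes)
        ]
        return pd.DataFrame(rows)


def shortest_path_induction(graph: nx.Graph, seeds) -> InducedNetwork:
    """Induce the subnetwork of all shortest paths between seed pairs.

    Node set = retained seeds plus every node on *any* geodesic between any
    seed pair (all ties kept); edge set = host-graph edges among those nodes.
    Seeds absent from the host graph are dropped with a logged warning;
    unreachable seed pairs are skipped with a logged count.
    """
    seeds = [normalize_symbol(s) for s in seeds]
    present = sorted(s for s in set(seeds) if s in graph)
    dropped = tuple(sorted(set(seeds) - set(present)))
    if dropped:
        logger.warning("seeds absent from host graph, dropped: %s", list(dropped))
    if len(present) < 2:
        raise ValidationError(f"need >= 2 seeds present in the graph; got {len(present)}")

    dist = {s: nx.single_source_shortest_path_length(graph, s) for s in present}
    nodes: set[str] = set(present)
    skipped = 0
    for s, t in combinations(present, 2):
        d_st = dist[s].get(t)
        if d_st is None:
            skipped += 1
            continue
        ds, dt = dist[s], dist[t]
        nodes.update(
            v for v, dv in ds.items() if dv <= d_st and dt.get(v, d_st + 1) + dv == d_st
        )
    if skipped:
        logger.info("skipped %d unreachable seed pair(s)", skipped)
    sub = nx.Graph(graph.subgraph(nodes))
    roles = {n: ("seed" if n in set(present) else "connector") for n in sub.nodes}
    return InducedNetwork(graph=sub, roles=roles, dropped_seeds=dropped, skipped_pairs=skipped)


# ---------------------------------------------------------------------------
# random walk with restart


@dataclass(frozen=True)
class PropagationResult:
    """RWR score vector with provenance; scores are >= 0 and sum to 1."""

    scores: dict[str, float]
    seeds: tuple[str, ...]
    alpha: float
    iterations: int
    converged: bool
    residual: float

    def top(self, k: int) -> tuple[str, ...]:
        """Top-k nodes by score, ties broken lexicographically by symbol."""
        ordered = sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return tuple(name for name, _ in ordered[:k])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"node": list(self.scores), "rwr_score": list(self.scores.values())}
        )
        df["is_seed"] = df["node"].isin(self.seeds)
        return df.sort_values(["rwr_score", "node"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)


def random_walk_restart(
    graph: nx.Graph,
    seeds,
    alpha: float = 0.15,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    normalization: str = "column",
) -> PropagationResult:
    """Random walk with restart from the seed set.

    Iterates ``s <- alpha*e + (1-alpha)*W s`` with e uniform over seeds and W
    the column-normalized adjacency ("column", default) or the symmetric
    normalization D^-1/2 A D^-1/2 ("symmetric").  Isolated nodes have no
    outgoing edges; their walk mass is returned to the restart distribution so
    the score vector keeps summing to 1.  ``alpha = 1`` returns the restart
    distribution exactly.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"restart probability alpha must be in (0, 1]; got {alpha}")
    if normalization not in ("column", "symmetric"):
        raise ValidationError(f"unknown normalization {normalization!r}")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    seeds = sorted({normalize_symbol(s) for s in seeds})
    present = [s for s in seeds if s in index]
    if not present:
        raise ValidationError("no seed is present in the graph")
    if len(present) < len(seeds):
        logger.warning("RWR seeds absent from graph, dropped: %s",
                       sorted(set(seeds) - set(present)))

    A = nx.to_numpy_array(graph, nodelist=nodes, dtype=float)
    deg = A.sum(axis=0)
    dangling = deg == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        if normalization == "column":
            W = np.where(dangling[None, :], 0.0, A / np.where(dangling, 1.0, deg)[None, :])
        else:
            d_inv_sqrt = np.where(dangling, 0.0, 1.0 / np.sqrt(np.where(dangling, 1.0, deg)))
            W = d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]

    e = np.zeros(len(nodes))
    for s in present:
        e[index[s]] = 1.0 / len(present)

    s_vec = e.copy()
    converged = False
    residual = 0.0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        lost = float(s_vec[dangling].sum()) if dangling.any() else 0.0
        s_new = alpha * e + (1.0 - alpha) * (W @ s_vec + lost * e)
        if normalization == "symmetric":
            s_new = s_new / s_new.sum()
        residual = float(np.abs(s_new - s_vec).sum())
        s_vec = s_new
        if residual < tol:
            converged = True
            break
    if not converged:
        logger.warning("RWR did not converge after %d iterations (residual %.3e)",
                       max_iter, residual)
    scores = {n: float(s_vec[index[n]]) for n in nodes}
    return PropagationResult(
        scores=scores,
        seeds=tuple(present),
        alpha=alpha,
        iterations=iterations,
        converged=converged,
        residual=residual,
    )


def identify_module(prop: PropagationResult, graph: nx.Graph, k: int | None = None) -> tuple[str, ...]:
    """Largest connected component of the top-k propagation scorers.

    Ties in score break lexicographically by symbol; size ties between
    components prefer the component containing more seeds, then the
    lexicographically smallest node set.  ``k`` defaults to twice the number
    of seeds and is clamped to the graph size with a warning.
    """
    if k is None:
        k = 2 * len(prop.seeds)
    if k < 1:
        raise ValidationError(f"module size k must be >= 1; got {k}")
    if k > graph.number_of_nodes():
        warnings.warn(
            f"k={k} exceeds graph size {graph.number_of_nodes()}; clamped",
            stacklevel=2,
        )
        k = graph.number_of_nodes()
    top = set(prop.top(k))
    sub = graph.subgraph(top)
    seed_set = set(prop.seeds)
    components = [tuple(sorted(c)) for c in nx.connected_components(sub)]
    components.sort(key=lambda c: (-len(c), -len(seed_set & set(c)), c))
    return components[0]


# ---------------------------------------------------------------------------
# annotation & pathway subnetworks


def annotate_with_fc(net: InducedNetwork, fc: pd.DataFrame, mapping: GeneMapping) -> InducedNetwork:
    """Attach fold-change annotations to the measured (seed) nodes.

    ``fc`` is a frame indexed by analyte with an ``fc`` column (the output of
    :func:`lithnet.group_stats.fold_change`).  A gene fed by several analytes
    (collapse group) carries the arithmetic mean of their fold changes;
    connectors carry None.
    """
    annotations: dict[str, float | None] = {}
    for node in net.graph.nodes:
        if net.roles[node] != "seed":
            annotations[node] = None
            continue
        analytes = mapping.analytes_for(node)
        if not analytes:
            raise ValidationError(f"measured node {node!r} has no source analytes in mapping")
        missing = [a for a in analytes if a not in fc.index]
        if missing:
            raise ValidationError(f"no fold change for analytes {missing} (gene {node})")
        annotations[node] = float(np.mean([fc.loc[a, "fc"] for a in analytes]))
    return replace(net, fc=annotations)


def extract_pathway_subnetwork(net: InducedNetwork, pathway) -> InducedNetwork:
    """Restrict an induced network to one pathway.

    Keeps the pathway genes present in the network plus any of the network's
    connector nodes lying on a shortest path (within the network) between two
    retained pathway genes; roles, fold changes and scores are preserved.  An
    empty intersection returns an empty network with a warning.
    """
    pathway = {normalize_symbol(g) for g in pathway}
    retained = sorted(pathway & set(net.graph.nodes))
    if not retained:
        warnings.warn("pathway has no genes in the network; returning empty network",
                      stacklevel=2)
        return InducedNetwork(graph=nx.Graph(), roles={}, fc={}, scores={})
    nodes: set[str] = set(retained)
    if len(retained) >= 2:
        dist = {s: nx.single_source_shortest_path_length(net.graph, s) for s in retained}
        connectors = set(net.connectors())
        for s, t in combinations(retained, 2):
            d_st = dist[s].get(t)
            if d_st is None:
                continue
            ds, dt = dist[s], dist[t]
            nodes.update(
                v
                for v in connectors
                if ds.get(v, d_st + 1) + dt.get(v, d_st + 1) == d_st
            )
    sub = nx.Graph(net.graph.subgraph(nodes))
    return InducedNetwork(
        graph=sub,
        roles={n: net.roles[n] for n in sub.nodes},
        fc={n: net.fc.get(n) for n in sub.nodes},
        scores={n: net.scores[n] for n in sub.nodes if n in net.scores},
    )
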