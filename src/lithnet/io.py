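"""Readers and writers for every external format the pipeline touches.

Formats
-------
* expression tables: long-format TSV with columns
  ``subject_id, group, timepoint, cell_type, analyte, mfr``
* interactomes: two-column tab-delimited edge lists, or a BioGRID-style
  export with ``Official Symbol Interactor A/B`` columns
* pathway gene sets: GMT
* annotated networks: GraphML, SIF or a plain edge-list TSV

All readers validate strictly and raise :class:`~lithnet.errors.FormatError`
or :class:`~lithnet.errors.ValidationError`; every reader is total on the
output of the corresponding writer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from ._symbols import normalize_symbol
from .errors import FormatError, ValidationError
from .panel import AnalytePanel

logger = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "TIMEPOINTS",
    "EXPRESSION_COLUMNS",
    "ExpressionTable",
    "GeneSetCollection",
    "read_expression_table",
    "read_edgelist",
    "write_edgelist",
    "read_gmt",
    "write_gmt",
    "write_network",
    "read_network_graphml",
]

GROUPS = ("responder", "nonresponder")
TIMEPOINTS = ("baseline", "post")
EXPRESSION_COLUMNS = ("subject_id", "group", "timepoint", "cell_type", "analyte", "mfr")

_KEY = ["subject_id", "timepoint", "cell_type", "analyte"]


@dataclass(frozen=True)
class ExpressionTable:
    """Validated long-format MFR observations.

    MFR (median fluorescence ratio) is the analyte signal normalized to a
    fluorescence-minus-one control; MFR = 1 means no detectable signal, so
    every value is >= 1.  The key (subject, timepoint, cell type, analyte)
    is unique.
    """

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame, panel: AnalytePanel | None = None) -> "ExpressionTable":
        missing = set(EXPRESSION_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"expression table missing columns: {sorted(missing)}")
        df = df.loc[:, list(EXPRESSION_COLUMNS)].copy()
        for col in ("subject_id", "group", "timepoint", "cell_type", "analyte"):
            df[col] = df[col].astype(str)
        df["mfr"] = pd.to_numeric(df["mfr"], errors="raise").astype(float)

        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValidationError(f"unknown timepoints: {sorted(bad_tp)}")
        if (df["mfr"] < 1.0).any():
            offenders = df.loc[df["mfr"] < 1.0]
            raise ValidationError(
                f"{len(offenders)} rows violate the MFR >= 1 floor "
                f"(first: {offenders.iloc[0].to_dict()})"
            )
        dup = df.duplicated(subset=_KEY)
        if dup.any():
            raise ValidationError(
                f"duplicated (subject, timepoint, cell_type, analyte) keys: "
                f"{df.loc[dup, _KEY].head().to_dict('records')}"
            )
        if panel is not None:
            unknown = sorted(set(df["analyte"]) - set(panel.analytes))
            if unknown:
                raise ValidationError(f"analytes not in panel: {unknown}")
        # A subject may appear in only one group.
        grp = df.groupby("subject_id")["group"].nunique()
        if (grp > 1).any():
            raise ValidationError(
                f"subjects assigned to more than one group: {sorted(grp[grp > 1].index)}"
            )
        df = df.sort_values(by=["timepoint", "cell_type", "group", "subject_id", "analyte"],
                            kind="mergesort").reset_index(drop=True)
        return cls(data=df)

    # -- accessors ---------------------------------------------------------

    def subjects(self, group: str | None = None, timepoint: str | None = None) -> tuple[str, ...]:
        df = self.data
        if group is not None:
            df = df[df["group"] == group]
        if timepoint is not None:
            df = df[df["timepoint"] == timepoint]
        return tuple(sorted(df["subject_id"].unique()))

    def paired_subjects(self, group: str) -> tuple[str, ...]:
        """Subjects of *group* with records at both timepoints."""
        base = set(self.subjects(group, "baseline"))
        post = set(self.subjects(group, "post"))
        return tuple(sorted(base & post))

    def cell_types(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["cell_type"].unique()))

    def analytes(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["analyte"].unique()))

    def has_timepoint(self, timepoint: str) -> bool:
        return bool((self.data["timepoint"] == timepoint).any())

    def wide(
        self,
        cell_type: str,
        group: str,
        timepoint: str,
        subjects: tuple[str, ...] | None = None,
    ) -> pd.DataFrame:
        """Subjects x analytes matrix for one stratum."""
        df = self.data
        mask = (
            (df["cell_type"] == cell_type)
            & (df["group"] == group)
            & (df["timepoint"] == timepoint)
        )
        sub = df.loc[mask]
        if subjects is not None:
            sub = sub[sub["subject_id"].isin(subjects)]
        if sub.empty:
            raise ValidationError(
                f"no records for stratum ({cell_type}, {group}, {timepoint})"
            )
        wide = sub.pivot(index="subject_id", columns="analyte", values="mfr")
        return wide.sort_index()

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=False, float_format="%.12g")
        return path

    def __len__(self) -> int:
        return len(self.data)


def read_expression_table(path: str | Path, panel: AnalytePanel | None = None) -> ExpressionTable:
    """Read and validate a long-format expression TSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression table") from exc
    return ExpressionTable.from_frame(df, panel=panel)


# ---------------------------------------------------------------------------
# interaction graphs


_BIOGRID_A = "official symbol interactor a"
_BIOGRID_B = "official symbol interactor b"


def read_edgelist(path: str | Path) -> nx.Graph:
    """Read an undirected gene-symbol interaction graph.

    Accepts a plain two-column tab-delimited edge list or a BioGRID-style
    export whose header contains ``Official Symbol Interactor A/B`` columns.
    Symbols are normalized, self-loops dropped (with a logged count) and
    duplicate edges collapsed.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty edge list")

    header = [c.strip().lower() for c in lines[0].split("\t")]
    pairs: list[tuple[str, str]] = []
    if _BIOGRID_A in header and _BIOGRID_B in header:
        ia, ib = header.index(_BIOGRID_A), header.index(_BIOGRID_B)
        for num, ln in enumerate(lines[1:], start=2):
            fields = ln.split("\t")
            if len(fields) <= max(ia, ib):
                raise FormatError(f"{path}:{num}: row shorter than header")
            pairs.append((fields[ia], fields[ib]))
    else:
        for num, ln in enumerate(lines, start=1):
            fields = ln.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{num}: expected 2 tab-delimited columns, got {len(fields)}"
                )
            pairs.append((fields[0], fields[1]))

    graph = nx.Graph()
    self_loops = 0
    for a, b in pairs:
        a, b = normalize_symbol(a), normalize_symbol(b)
        if not a or not b:
            raise FormatError(f"{path}: empty gene symbol in edge ({a!r}, {b!r})")
        if a == b:
            self_loops += 1
            continue
        graph.add_edge(a, b)
    if self_loops:
        logger.info("%s: dropped %d self-loop(s)", path, self_loops)
    dupes = len(pairs) - self_loops - graph.number_of_edges()
    if dupes:
        logger.info("%s: collapsed %d duplicate edge(s)", path, dupes)
    if graph.number_of_edges() == 0:
        raise FormatError(f"{path}: no edges after normalization")
    return graph


def write_edgelist(graph: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")
    return path


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathway gene sets with normalized symbols."""

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> tuple[str, ...]:
        return tuple(self.sets)

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one tab-delimited line per set (name, description, genes...)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    for num, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{num}: GMT line needs name, description and >=1 gene")
        name, desc, *genes = fields
        if name in sets:
            raise FormatError(f"{path}:{num}: duplicate gene-set name {name!r}")
        if any(not g.strip() for g in genes):
            raise FormatError(f"{path}:{num}: empty gene field")
        members = frozenset(normalize_symbol(g) for g in genes)
        sets[name] = members
        descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")
    return path


# ---------------------------------------------------------------------------
# annotated networks

NETWORK_FORMATS = ("graphml", "sif", "edgelist-tsv")

#: GraphML cannot carry a native null, so a null fold change (unmeasured
#: node) is serialized by omitting the attribute entirely, never as 0.


def write_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Write an annotated graph.

    Node attributes with value ``None`` (e.g. the fold change of an
    unmeasured connector node) are omitted from GraphML output and written
    as ``NA`` in the edge-list TSV node section; they are never coerced to 0.
    """
    path = Path(path)
    if fmt not in NETWORK_FORMATS:
        raise ValidationError(f"unknown network format {fmt!r}; choose from {NETWORK_FORMATS}")
    if fmt == "graphml":
        clean = nx.Graph()
        for node in sorted(graph.nodes):
            attrs = {k: v for k, v in graph.nodes[node].items() if v is not None}
            clean.add_node(node, **attrs)
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            clean.add_edge(a, b)
        nx.write_graphml(clean, path)
    elif fmt == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
                fh.write(f"{a}\tpp\t{b}\n")
    else:  # edgelist-tsv
        write_edgelist(graph, path)
    return path


def read_network_graphml(path: str | Path) -> nx.Graph:
    """Read a GraphML network, restoring absent fold-change attributes to None."""
    graph = nx.read_graphml(Path(path))
    graph = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    for node in graph.nodes:
        if "fc" not in graph.nodes[node]:
            graph.nodes[node]["fc"] = None
    return nx.Graph(graph)
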