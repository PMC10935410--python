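"""End-to-end orchestration: synthetic inputs or real files in, a
deterministic artifact directory out.

Stage order mirrors the analysis: fold changes and t-tests, per-stratum
correlation grids, anchor before/after profiles, analyte-to-gene collapse,
shortest-path network induction, random-walk-with-restart propagation,
module identification, pathway enrichment, and per-pathway subnetworks.  A
run manifest (JSON) with per-stage counts and warnings is emitted on every
run, success or failure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _version
from ._symbols import normalize_symbol
from .correlation import anchor_profile, pairwise_correlation
from .enrichment import build_universe, enrich_all, rows_to_frame
from .errors import ConfigError, LithnetError, ValidationError
from .group_stats import fold_change, paired_ttests, unpaired_ttests
from .io import (
    ExpressionTable,
    read_edgelist,
    read_expression_table,
    read_gmt,
    write_edgelist,
    write_gmt,
    write_network,
)
from .network import (
    annotate_with_fc,
    default_mapping,
    extract_pathway_subnetwork,
    identity_mapping,
    identify_module,
    map_analytes_to_genes,
    random_walk_restart,
    read_mapping,
    shortest_path_induction,
    write_mapping,
)
from .panel import DEFAULT_ANCHORS, DEFAULT_PANEL, AnalytePanel
from .synthetic import (
    CohortConfig,
    GeneSetPlantConfig,
    InteractomeConfig,
    apply_treatment_effect,
    generate_cohort,
    generate_genesets,
    generate_interactome,
)

__all__ = ["PipelineConfig", "InputPaths", "SyntheticInputs",
           "make_demo_config", "run_pipeline", "config_from_yaml"]


@dataclass(frozen=True)
class InputPaths:
    """Real-input mode: paths to the four external files."""

    expression: str
    edgelist: str
    gmt: str
    mapping: str | None = None  # None -> shipped default mapping


@dataclass(frozen=True)
class SyntheticInputs:
    """Synthetic mode: generator configurations."""

    cohort: CohortConfig
    interactome: InteractomeConfig
    genesets: GeneSetPlantConfig


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration; every analysis gap surfaces as a key."""

    outdir: str
    seed: int | None = None
    synthetic: SyntheticInputs | None = None
    inputs: InputPaths | None = None
    anchors: tuple[str, ...] = DEFAULT_ANCHORS
    alpha: float = 0.15
    module_k: int | None = None  # None -> 2 x number of seeds
    universe_rule: str = "graph-geneset-intersection"
    levels: tuple[float, ...] = (0.05, 0.01)
    log_transform: bool = False
    bh_adjust: bool = False
    fc_mean: str = "arithmetic"
    equal_var: bool = False
    enrich_target: str = "module"  # or "network"
    post_correlation_groups: tuple[str, ...] = ("responder",)
    fc_cell_type: str | None = None  # None -> first cell type
    subnetwork_p: float = 0.05
    max_subnetworks: int = 4
    mapping_convention: str = "figure"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("exactly one of synthetic configs or input paths must be set")
        if self.synthetic is not None and self.seed is None:
            raise ConfigError("seed is mandatory in synthetic mode")
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigError("alpha must lie in (0, 1]")
        if self.enrich_target not in ("module", "network"):
            raise ConfigError("enrich_target must be 'module' or 'network'")
        if self.fc_mean not in ("arithmetic", "geometric"):
            raise ConfigError("fc_mean must be 'arithmetic' or 'geometric'")


def make_demo_config(seed: int, outdir: str | Path) -> PipelineConfig:
    """A synthetic configuration at the study's scale.

    28 analytes in two cell types; 12 responders and 11 non-responders at
    baseline; 9 responders and 4 non-responders with post-treatment samples;
    a 200-node interactome containing the 23 mapped genes; 50 gene sets with
    one planted pathway.
    """
    mapping = default_mapping()
    genes, _ = map_analytes_to_genes(DEFAULT_PANEL, mapping)
    return PipelineConfig(
        outdir=str(outdir),
        seed=int(seed),
        synthetic=SyntheticInputs(
            cohort=CohortConfig(rng_seed=int(seed)),
            interactome=InteractomeConfig(n_nodes=200, attachment_edges=3,
                                          must_include=genes, rng_seed=int(seed) + 1),
            genesets=GeneSetPlantConfig(rng_seed=int(seed) + 2),
        ),
    )


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a declarative YAML file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    synthetic = None
    if "synthetic" in raw:
        s = raw.pop("synthetic")
        for section in ("cohort", "interactome", "genesets"):
            entry = s.setdefault(section, {})
            for key in ("cell_types", "must_include", "analytes"):
                if key in entry and entry[key] is not None:
                    entry[key] = tuple(entry[key])
        synthetic = SyntheticInputs(
            cohort=CohortConfig(**s["cohort"]),
            interactome=InteractomeConfig(**s["interactome"]),
            genesets=GeneSetPlantConfig(**s["genesets"]),
        )
    inputs = InputPaths(**raw.pop("inputs")) if "inputs" in raw else None
    for key in ("anchors", "levels", "post_correlation_groups"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(synthetic=synthetic, inputs=inputs, **raw)
    cfg.validate()
    return cfg


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = asdict(config)
    return snap


def _write_frame(df, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.12g")


def _safe_name(label: str) -> str:
    out = normalize_symbol(label)
    return "".join(c if c.isalnum() or c in "._" else "_" for c in out)


@dataclass
class _Manifest:
    config: dict = field(default_factory=dict)
    version: str = _version
    status: str = "running"
    failed_stage: str | None = None
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, outdir: Path) -> None:
        payload = {
            "version": self.version,
            "status": self.status,
            "failed_stage": self.failed_stage,
            "config": self.config,
            "counts": self.counts,
            "warnings": self.warnings,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True, default=str), encoding="utf-8"
        )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the artifact directory.

    Identical config and seed produce byte-identical tabular outputs.  Any
    stage error aborts with the stage name recorded in the manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config=_config_snapshot(config))
    stage = "inputs"
    try:
        # ---------------------------------------------------------- inputs
        if config.synthetic is not None:
            cohort_cfg = config.synthetic.cohort
            table = apply_treatment_effect(generate_cohort(cohort_cfg), cohort_cfg)
            analyte_names = cohort_cfg.analyte_names()
            if analyte_names == DEFAULT_PANEL.analytes:
                mapping = default_mapping(convention=config.mapping_convention)
                panel = DEFAULT_PANEL
            else:
                mapping = identity_mapping(analyte_names)
                panel = AnalytePanel(analytes=analyte_names)
            seeds_for_plant, _ = map_analytes_to_genes(panel, mapping)
            inter_cfg = config.synthetic.interactome
            if not inter_cfg.must_include:
                inter_cfg = replace(inter_cfg, must_include=seeds_for_plant)
            graph = generate_interactome(inter_cfg)
            gene_sets = generate_genesets(graph, seeds_for_plant, config.synthetic.genesets)
            table.write_tsv(outdir / "expression.tsv")
            write_edgelist(graph, outdir / "interactome_edges.tsv")
            write_gmt(gene_sets, outdir / "genesets.gmt")
            write_mapping(mapping, outdir / "mapping.tsv")
        else:
            paths = config.inputs
            mapping = (read_mapping(paths.mapping) if paths.mapping
                       else default_mapping(convention=config.mapping_convention))
            analyte_names = tuple(r.analyte for r in mapping.rows)
            panel = (DEFAULT_PANEL if set(analyte_names) == set(DEFAULT_PANEL.analytes)
                     else AnalytePanel(analytes=analyte_names))
            table = read_expression_table(paths.expression, panel=panel)
            graph = read_edgelist(paths.edgelist)
            gene_sets = read_gmt(paths.gmt)
        manifest.counts["expression_rows"] = len(table)
        manifest.counts["interactome_nodes"] = graph.number_of_nodes()
        manifest.counts["interactome_edges"] = graph.number_of_edges()
        manifest.counts["gene_sets"] = len(gene_sets)
        cell_types = table.cell_types()
        analyte_order = tuple(a for a in panel.analytes if a in set(table.analytes()))

        # ------------------------------------------------------ group stats
        stage = "group_stats"
        fc_by_cell = {}
        for ct in cell_types:
            fc = fold_change(table, ct, "baseline", mean=config.fc_mean)
            fc = fc.loc[list(analyte_order)]
            fc_by_cell[ct] = fc
            _write_frame(fc, outdir / f"fold_change_baseline.{_safe_name(ct)}.tsv", index=True)
        _write_frame(unpaired_ttests(table, equal_var=config.equal_var),
                     outdir / "ttests_unpaired_baseline.tsv")
        paired_frames = []
        for group in ("responder", "nonresponder"):
            n_pairs = len(table.paired_subjects(group))
            if n_pairs >= 2:
                paired_frames.append(paired_ttests(table, group=group).assign(group=group))
            else:
                manifest.warnings.append(
                    f"paired t-tests skipped for {group}: only {n_pairs} paired subject(s)"
                )
        if paired_frames:
            _write_frame(pd.concat(paired_frames, ignore_index=True),
                         outdir / "ttests_paired.tsv")

        # ------------------------------------------------------ correlation
        stage = "correlation"
        grid_counts = {}
        strata = [(ct, g, "baseline") for ct in cell_types for g in ("responder", "nonresponder")]
        if table.has_timepoint("post"):
            for ct in cell_types:
                for g in ("responder", "nonresponder"):
                    if g not in config.post_correlation_groups:
                        manifest.warnings.append(
                            f"post-treatment correlation skipped for {g} ({ct}): "
                            f"only {len(table.paired_subjects(g))} paired subject(s) "
                            "available; group not configured for post-treatment analysis"
                        )
                        continue
                    strata.append((ct, g, "post"))
        for ct, group, tp in strata:
            subjects = table.paired_subjects(group) if tp == "post" else None
            n = len(subjects) if subjects is not None else len(table.subjects(group, tp))
            if n < 3:
                manifest.warnings.append(
                    f"correlation grid skipped for ({ct}, {group}, {tp}): {n} subject(s) < 3"
                )
                continue
            grid = pairwise_correlation(table, ct, group, tp, analytes=analyte_order,
                                        subjects=subjects, log_transform=config.log_transform)
            key = f"{_safe_name(ct)}.{group}.{tp}"
            for which in ("r2", "p", "class"):
                _write_frame(grid.to_frame(which), outdir / f"correlation.{key}.{which}.tsv",
                             index=True)
            grid_counts[key] = {str(lv): grid.count_significant(lv) for lv in config.levels}
        manifest.counts["correlation_grids"] = grid_counts

        # ---------------------------------------------------- anchor profiles
        stage = "anchor_profiles"
        anchor_counts = {}
        for group in config.post_correlation_groups:
            n_paired = len(table.paired_subjects(group))
            if n_paired < 3 or not table.has_timepoint("post"):
                manifest.warnings.append(
                    f"anchor profiles refused for {group}: {n_paired} paired subject(s) < 3"
                )
                continue
            for anchor in config.anchors:
                if anchor not in analyte_order:
                    manifest.warnings.append(f"anchor {anchor!r} not in panel; skipped")
                    continue
                for ct in cell_types:
                    profile = anchor_profile(table, anchor, ct, group,
                                             analytes=analyte_order,
                                             log_transform=config.log_transform)
                    name = f"anchor.{_safe_name(anchor)}.{_safe_name(ct)}.{group}"
                    _write_frame(profile.to_frame(), outdir / f"{name}.tsv")
                    anchor_counts[name] = {
                        "baseline": profile.count_significant(0.05, "baseline"),
                        "post": profile.count_significant(0.05, "post"),
                    }
        manifest.counts["anchor_profiles"] = anchor_counts

        # ---------------------------------------------------------- network
        stage = "network"
        seeds, excluded = map_analytes_to_genes(panel, mapping)
        manifest.counts["mapped_genes"] = len(seeds)
        manifest.counts["excluded_analytes"] = list(excluded)
        net = shortest_path_induction(graph, seeds)
        if net.dropped_seeds:
            manifest.warnings.append(f"seeds absent from interactome: {list(net.dropped_seeds)}")
        if net.skipped_pairs:
            manifest.warnings.append(f"unreachable seed pairs skipped: {net.skipped_pairs}")
        prop = random_walk_restart(graph, seeds, alpha=config.alpha)
        if not prop.converged:
            manifest.warnings.append(
                f"propagation not converged (residual {prop.residual:.3e})"
            )
        k = config.module_k if config.module_k is not None else 2 * len(prop.seeds)
        module = identify_module(prop, graph, k=k)
        fc_cell = config.fc_cell_type or cell_types[0]
        net = annotate_with_fc(net, fc_by_cell[fc_cell], mapping)
        net = replace(net, scores={n: prop.scores[n] for n in net.graph.nodes})
        annotated = net.to_graph()
        write_network(annotated, outdir / "induced_network.graphml", "graphml")
        write_network(annotated, outdir / "induced_network.sif", "sif")
        _write_frame(net.node_table(), outdir / "induced_network.nodes.tsv")
        _write_frame(prop.to_frame(), outdir / "rwr_scores.tsv")
        (outdir / "module.txt").write_text("\n".join(module) + "\n", encoding="utf-8")
        manifest.counts["induced_nodes"] = net.graph.number_of_nodes()
        manifest.counts["induced_edges"] = net.graph.number_of_edges()
        manifest.counts["induced_connectors"] = len(net.connectors())
        manifest.counts["module_size"] = len(module)
        manifest.counts["rwr_iterations"] = prop.iterations

        # ------------------------------------------------------- enrichment
        stage = "enrichment"
        universe = build_universe(config.universe_rule, graph=graph, gene_sets=gene_sets)
        target = module if config.enrich_target == "module" else net.nodes()
        rows = enrich_all(target, gene_sets, universe, adjust=config.bh_adjust)
        _write_frame(rows_to_frame(rows), outdir / "enrichment.tsv")
        manifest.counts["universe_size"] = len(universe)
        manifest.counts["enriched_pathways_p05"] = sum(1 for r in rows if r.p <= 0.05)
        manifest.counts["top_pathway"] = rows[0].pathway if rows else None

        # ------------------------------------------------------ subnetworks
        stage = "subnetworks"
        chosen = [r for r in rows if r.p <= config.subnetwork_p][: config.max_subnetworks]
        subnet_counts = {}
        for row in chosen:
            sub = extract_pathway_subnetwork(net, gene_sets[row.pathway])
            name = _safe_name(row.pathway)
            write_network(sub.to_graph(), outdir / f"subnetwork.{name}.graphml", "graphml")
            subnet_counts[row.pathway] = sub.graph.number_of_nodes()
        manifest.counts["subnetworks"] = subnet_counts

        manifest.status = "success"
        manifest.failed_stage = None
        return outdir
    except LithnetError:
        manifest.status = "failed"
        manifest.failed_stage = stage
        raise
    except Exception:
        manifest.status = "failed"
        manifest.failed_stage = stage
        raise
    finally:
        manifest.write(outdir)
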