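"""Synthetic cohorts, interactomes and pathway gene sets.

The cohort generator emulates the statistical structure of a two-group
(responder / non-responder) intracellular flow-cytometry study:

* MFR values live on the scale ``1 + exp(z)`` so the "no signal" floor
  MFR = 1 is approached but never crossed;
* within-group correlation between analytes comes from one shared latent
  factor per group: ``z = mu + L_g * f_subject * w_analyte + eps``.  Subject
  factor scores are shared across cell types while analyte weights are
  cell-type specific, so correlation patterns differ between cell types;
* the log-signal mean is variance-calibrated (``mu_eff = mu - sigma_z**2/2``)
  so that ``E[MFR - 1] = exp(mu + group offset)`` regardless of the factor
  loading — the non-responder baseline elevation therefore controls the
  fold-change sign pattern independently of the correlation-strength knobs;
* treatment shifts the responder log-signal and damps the responder factor
  loading (post-treatment decorrelation); non-responders shift in the
  opposite direction with loading unchanged.

All randomness flows from a single integer seed through a fixed
``SeedSequence`` splitting scheme, so identical configs reproduce
byte-identical tables and graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._symbols import normalize_symbol
from .errors import ConfigError, ValidationError
from .io import ExpressionTable, GeneSetCollection
from .panel import DEFAULT_PANEL

__all__ = [
    "CohortConfig",
    "InteractomeConfig",
    "GeneSetPlantConfig",
    "PLANTED_SET_NAME",
    "generate_cohort",
    "apply_treatment_effect",
    "generate_interactome",
    "generate_genesets",
]

PLANTED_SET_NAME = "PW_PLANTED"


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic two-group cohort.

    Defaults reproduce the study scale: 12 responders / 11 non-responders at
    baseline over 28 analytes in two cell types, with 9 responders and 4
    non-responders carrying post-treatment samples, responders more
    correlated at baseline, non-responders elevated at baseline, and
    opposite-signed treatment shifts with post-treatment decorrelation in
    responders.
    """

    n_responders: int = 12
    n_nonresponders: int = 11
    n_analytes: int = 28
    cell_types: tuple[str, ...] = ("CD4", "monocyte")
    baseline_mean_offset_nonresp: float = 0.5
    factor_loading_resp: float = 1.0
    factor_loading_nonresp: float = 0.3
    # noise_sd calibrated so the baseline anchor profile yields roughly half
    # of the 27 possible significant correlations at n = 9 (the density the
    # analysis is designed around), rather than a saturated grid
    noise_sd: float = 0.4
    treatment_shift_resp: float = 0.5
    treatment_shift_nonresp: float = -0.5
    post_decorrelation_resp: float = 0.25
    n_post_responders: int | None = 9
    n_post_nonresponders: int | None = 4
    analytes: tuple[str, ...] | None = None
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_responders < 2 or self.n_nonresponders < 2:
            raise ConfigError("each group needs >= 2 subjects")
        if self.n_analytes < 2:
            raise ConfigError("need >= 2 analytes")
        if not self.cell_types:
            raise ConfigError("need >= 1 cell type")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.factor_loading_resp < 0 or self.factor_loading_nonresp < 0:
            raise ConfigError("factor loadings must be >= 0")
        if not (0.0 <= self.post_decorrelation_resp <= 1.0):
            raise ConfigError("post_decorrelation_resp must lie in [0, 1]")
        for n_post, n_grp, label in (
            (self.n_post_responders, self.n_responders, "responders"),
            (self.n_post_nonresponders, self.n_nonresponders, "non-responders"),
        ):
            if n_post is not None and not (0 <= n_post <= n_grp):
                raise ConfigError(f"n_post_{label} out of range")
        if self.analytes is not None and len(self.analytes) != self.n_analytes:
            raise ConfigError("analytes list must match n_analytes")

    def analyte_names(self) -> tuple[str, ...]:
        if self.analytes is not None:
            return self.analytes
        if self.n_analytes == len(DEFAULT_PANEL):
            return DEFAULT_PANEL.analytes
        return tuple(f"A{i + 1:02d}" for i in range(self.n_analytes))

    def subject_ids(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        resp = tuple(f"R{i + 1:02d}" for i in range(self.n_responders))
        nonresp = tuple(f"N{i + 1:02d}" for i in range(self.n_nonresponders))
        return resp, nonresp


def latent_state(config: CohortConfig) -> dict:
    """Deterministic latent parameters and subject factor scores.

    Splitting scheme: one ``SeedSequence(rng_seed)`` spawns, in order, the
    streams for analyte means, analyte weights, subject factors, baseline
    noise and post-treatment noise.
    """
    config.validate()
    ss = np.random.SeedSequence(config.rng_seed)
    k_mu, k_w, k_f, k_eb, k_ep = ss.spawn(5)
    a = config.n_analytes
    mu = np.random.default_rng(k_mu).normal(1.0, 0.4, size=a)
    rng_w = np.random.default_rng(k_w)
    weights = {}
    for ct in config.cell_types:
        mag = rng_w.uniform(0.5, 1.0, size=a)
        sign = rng_w.choice((-1.0, 1.0), size=a)
        weights[ct] = mag * sign
    resp, nonresp = config.subject_ids()
    subjects = resp + nonresp
    f = np.random.default_rng(k_f).standard_normal(len(subjects))
    factors = dict(zip(subjects, f))
    return {
        "mu": mu,
        "weights": weights,
        "factors": factors,
        "noise_key_baseline": k_eb,
        "noise_key_post": k_ep,
    }


def _records(
    config: CohortConfig,
    state: dict,
    timepoint: str,
    subjects_by_group: dict[str, tuple[str, ...]],
    rng_noise: np.random.Generator,
) -> pd.DataFrame:
    analytes = config.analyte_names()
    mu = state["mu"]
    rows = []
    for group in ("responder", "nonresponder"):
        loading = (
            config.factor_loading_resp if group == "responder" else config.factor_loading_nonresp
        )
        offset = 0.0 if group == "responder" else config.baseline_mean_offset_nonresp
        shift = 0.0
        if timepoint == "post":
            if group == "responder":
                shift = config.treatment_shift_resp
                loading = loading * config.post_decorrelation_resp
            else:
                shift = config.treatment_shift_nonresp
        for cell_type in config.cell_types:
            w = state["weights"][cell_type]
            sigma2 = (loading * w) ** 2 + config.noise_sd**2
            for subject in subjects_by_group[group]:
                f = state["factors"][subject]
                eps = rng_noise.normal(0.0, 1.0, size=config.n_analytes) * config.noise_sd
                z = mu + offset + shift - sigma2 / 2.0 + loading * f * w + eps
                mfr = 1.0 + np.exp(z)
                rows.extend(
                    {
                        "subject_id": subject,
                        "group": group,
                        "timepoint": timepoint,
                        "cell_type": cell_type,
                        "analyte": analyte,
                        "mfr": value,
                    }
                    for analyte, value in zip(analytes, mfr)
                )
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> ExpressionTable:
    """One baseline record per (subject, cell type, analyte)."""
    state = latent_state(config)
    resp, nonresp = config.subject_ids()
    rng = np.random.default_rng(state["noise_key_baseline"])
    df = _records(config, state, "baseline",
                  {"responder": resp, "nonresponder": nonresp}, rng)
    return ExpressionTable.from_frame(df)


def apply_treatment_effect(table: ExpressionTable, config: CohortConfig) -> ExpressionTable:
    """Add post-treatment records for the paired subset of each group.

    Responders shift by ``treatment_shift_resp`` with their factor loading
    damped by ``post_decorrelation_resp``; non-responders shift by
    ``treatment_shift_nonresp``.  Baseline records are unchanged.  The paired
    subset is the first ``n_post_*`` subjects of each group in subject-id
    order (all subjects when None).
    """
    if table.has_timepoint("post"):
        raise ValidationError("table already contains post-treatment records")
    state = latent_state(config)
    resp, nonresp = config.subject_ids()
    n_pr = len(resp) if config.n_post_responders is None else config.n_post_responders
    n_pn = len(nonresp) if config.n_post_nonresponders is None else config.n_post_nonresponders
    rng = np.random.default_rng(state["noise_key_post"])
    post = _records(config, state, "post",
                    {"responder": resp[:n_pr], "nonresponder": nonresp[:n_pn]}, rng)
    df = pd.concat([table.data, post], ignore_index=True)
    return ExpressionTable.from_frame(df)


# ---------------------------------------------------------------------------
# interactome


@dataclass(frozen=True)
class InteractomeConfig:
    """Preferential-attachment interactome with named required nodes.

    Preferential attachment gives the heavy-tailed degree distribution of
    real protein-interaction networks and a connected graph by construction.
    """

    n_nodes: int = 200
    attachment_edges: int = 3
    must_include: tuple[str, ...] = ()
    rng_seed: int = 0

    def validate(self) -> None:
        if self.attachment_edges < 1:
            raise ConfigError("attachment_edges must be >= 1")
        if self.n_nodes < self.attachment_edges + 1:
            raise ConfigError(
                f"n_nodes={self.n_nodes} must exceed attachment_edges={self.attachment_edges}"
            )
        if self.n_nodes < len(self.must_include):
            raise ConfigError("n_nodes smaller than the must_include list")


def generate_interactome(config: InteractomeConfig) -> nx.Graph:
    """Connected, simple, undirected scale-free graph over gene symbols."""
    config.validate()
    must = [normalize_symbol(s) for s in config.must_include]
    if len(set(must)) != len(must):
        raise ConfigError("must_include contains duplicate symbols after normalization")
    g = nx.barabasi_albert_graph(config.n_nodes, config.attachment_edges,
                                 seed=int(config.rng_seed))
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(1)[0])
    positions = rng.permutation(config.n_nodes)[: len(must)]
    labels: dict[int, str] = {}
    for pos, name in zip(positions, must):
        labels[int(pos)] = name
    width = len(str(config.n_nodes))
    for node in range(config.n_nodes):
        if node not in labels:
            labels[node] = f"G{node:0{width}d}"
    return nx.relabel_nodes(g, labels)


# ---------------------------------------------------------------------------
# gene sets with one planted pathway


@dataclass(frozen=True)
class GeneSetPlantConfig:
    """Random gene sets plus one pathway planted to overlap the seed module."""

    n_sets: int = 50
    size_min: int = 15
    size_max: int = 40
    planted_overlap: int = 12
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_sets < 1:
            raise ConfigError("n_sets must be >= 1")
        if not (1 <= self.size_min <= self.size_max):
            raise ConfigError("need 1 <= size_min <= size_max")
        if self.planted_overlap > self.size_min:
            raise ConfigError("planted_overlap must not exceed size_min")


def generate_genesets(graph: nx.Graph, module, config: GeneSetPlantConfig) -> GeneSetCollection:
    """Draw gene sets from the graph nodes, planting one set on the module.

    The planted set (named ``PW_PLANTED``) contains exactly
    ``planted_overlap`` genes from *module* plus fill drawn outside it, and is
    kept at the minimum configured size so the forced overlap stays the
    dominant fraction of its membership; the remaining ``n_sets - 1`` sets are
    uniform node samples whose sizes are drawn from [size_min, size_max].
    """
    config.validate()
    module = sorted({normalize_symbol(g) for g in module})
    nodes = sorted(graph.nodes)
    outside = [n for n in nodes if n not in set(module)]
    if set(module) - set(nodes):
        raise ValidationError(f"module genes absent from graph: {sorted(set(module) - set(nodes))}")
    if config.planted_overlap > len(module):
        raise ValidationError(
            f"planted_overlap={config.planted_overlap} exceeds module size {len(module)}"
        )
    rng = np.random.default_rng(config.rng_seed)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}

    size = max(config.size_min, config.planted_overlap)
    from_module = rng.choice(module, size=config.planted_overlap, replace=False)
    n_fill = min(size - config.planted_overlap, len(outside))
    fill = rng.choice(outside, size=n_fill, replace=False) if n_fill else []
    sets[PLANTED_SET_NAME] = frozenset(from_module) | frozenset(fill)
    descriptions[PLANTED_SET_NAME] = "synthetic pathway planted on the seed module"

    for i in range(config.n_sets - 1):
        name = f"PW_{i + 1:03d}"
        size = int(rng.integers(config.size_min, config.size_max + 1))
        members = rng.choice(nodes, size=min(size, len(nodes)), replace=False)
        sets[name] = frozenset(members)
        descriptions[name] = "synthetic random gene set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)
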