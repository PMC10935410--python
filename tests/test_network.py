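"""Gene mapping, shortest-path induction, propagation, modules and subnetworks."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lithnet.errors import ValidationError
from lithnet.network import (
    annotate_with_fc,
    default_mapping,
    extract_pathway_subnetwork,
    identify_module,
    map_analytes_to_genes,
    random_walk_restart,
    read_mapping,
    shortest_path_induction,
    write_mapping,
)
from lithnet.panel import DEFAULT_PANEL


def geodesic_node_union(graph, seeds):
    """Brute-force oracle: union of all nodes on any shortest path between seeds."""
    nodes = set(seeds)
    for s, t in itertools.combinations(sorted(seeds), 2):
        try:
            for path in nx.all_shortest_paths(graph, s, t):
                nodes.update(path)
        except nx.NetworkXNoPath:
            continue
    return nodes


def rwr_linear_solve(graph, seeds, alpha):
    """Direct-solve oracle for the restart walk: s = alpha (I - (1-a) W)^-1 e."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    A = nx.to_numpy_array(graph, nodelist=nodes, dtype=float)
    deg = A.sum(axis=0)
    W = np.zeros_like(A)
    nz = deg > 0
    W[:, nz] = A[:, nz] / deg[nz]
    e = np.zeros(len(nodes))
    for s in seeds:
        e[idx[s]] = 1.0 / len(seeds)
    # dangling columns redirect their mass to the restart distribution
    dangling = (~nz).astype(float)
    W_full = W + np.outer(e, dangling)
    s_vec = alpha * np.linalg.solve(np.eye(len(nodes)) - (1 - alpha) * W_full, e)
    return dict(zip(nodes, s_vec))


class TestMapping:
    def test_panel_collapses_to_23_genes_with_exclusions(self):
        genes, excluded = map_analytes_to_genes(DEFAULT_PANEL, default_mapping())
        assert len(genes) == 23
        assert set(excluded) == {"PDEB4", "XBP1"}
        assert "GSK3B" in genes and "FYN" in genes
        assert "PDE4B" not in genes and "XBP1" not in genes

    def test_collapse_groups_merge(self):
        mapping = default_mapping()
        gsk = {a for a in DEFAULT_PANEL if mapping.gene_for(a) == "GSK3B"}
        assert gsk == {"GSK3β", "phospho-GSK3β", "phospho-GSK3α/β"}
        fyn = {a for a in DEFAULT_PANEL if mapping.gene_for(a) == "FYN"}
        assert fyn == {"Fyn", "phospho-Fyn/phospho-Yes"}

    def test_hgnc_convention_swaps_three_symbols(self):
        genes, _ = map_analytes_to_genes(DEFAULT_PANEL, default_mapping(convention="hgnc"))
        assert len(genes) == 23
        assert {"RELA", "NOS2", "PRKACA"} <= set(genes)
        assert not {"NFKB1", "NOS1", "PRKCA"} & set(genes)

    def test_unmapped_analyte_rejected(self):
        mapping = default_mapping()
        trimmed = type(mapping)(rows=mapping.rows[:-1])
        with pytest.raises(ValidationError, match="absent from mapping"):
            map_analytes_to_genes(DEFAULT_PANEL, trimmed)

    def test_mapping_tsv_round_trip(self, tmp_path):
        mapping = default_mapping()
        path = write_mapping(mapping, tmp_path / "map.tsv")
        again = read_mapping(path)
        assert again.rows == mapping.rows


class TestInduction:
    def test_adjacent_seeds_only(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D")])
        net = shortest_path_induction(g, ["A", "B"])
        assert net.nodes() == ("A", "B")

    def test_path_connector_included(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        net = shortest_path_induction(g, ["A", "C"])
        assert net.nodes() == ("A", "B", "C")
        assert net.roles["B"] == "connector"
        assert net.seeds() == ("A", "C")

    def test_diamond_keeps_both_tied_geodesics(self):
        g = nx.Graph([("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")])
        net = shortest_path_induction(g, ["A", "D"])
        assert set(net.nodes()) == {"A", "B", "C", "D"}

    def test_matches_geodesic_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            nodes = sorted(g.nodes)
            k = int(rng.integers(2, min(5, n) + 1))
            seeds = list(rng.choice(nodes, size=k, replace=False))
            net = shortest_path_induction(g, seeds)
            assert set(net.nodes()) == geodesic_node_union(g, seeds)

    def test_absent_seeds_dropped_and_too_few_rejected(self):
        g = nx.Graph([("A", "B")])
        net = shortest_path_induction(g, ["A", "B", "ZZZ"])
        assert net.dropped_seeds == ("ZZZ",)
        with pytest.raises(ValidationError, match=">= 2 seeds"):
            shortest_path_induction(g, ["A", "ZZZ"])

    def test_induction_idempotent(self):
        g = nx.gnp_random_graph(20, 0.2, seed=3)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        seeds = sorted(g.nodes)[:5]
        net1 = shortest_path_induction(g, seeds)
        net2 = shortest_path_induction(net1.graph, seeds)
        assert net1.nodes() == net2.nodes()


class TestRandomWalk:
    def test_restart_only_limit_returns_seed_distribution(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        res = random_walk_restart(g, ["A", "C"], alpha=1.0)
        assert res.scores == {"A": 0.5, "B": 0.0, "C": 0.5}
        assert res.converged

    def test_two_node_closed_form(self):
        g = nx.Graph([("A", "B")])
        res = random_walk_restart(g, ["A"], alpha=0.5)
        assert res.scores["A"] == pytest.approx(2 / 3, abs=1e-9)
        assert res.scores["B"] == pytest.approx(1 / 3, abs=1e-9)

    @pytest.mark.parametrize("alpha", [0.15, 0.5, 0.9])
    def test_matches_direct_linear_solve(self, alpha):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(3, 30))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            seeds = list(rng.choice(sorted(g.nodes), size=int(rng.integers(1, 4)),
                                    replace=False))
            res = random_walk_restart(g, seeds, alpha=alpha)
            oracle = rwr_linear_solve(g, sorted(set(seeds)), alpha)
            for node, val in oracle.items():
                assert res.scores[node] == pytest.approx(val, abs=1e-8)
            assert sum(res.scores.values()) == pytest.approx(1.0, abs=1e-8)

    def test_seed_mass_monotone_in_alpha(self):
        g = nx.barabasi_albert_graph(40, 2, seed=1)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        seeds = sorted(g.nodes)[:4]
        masses = [
            sum(random_walk_restart(g, seeds, alpha=a).scores[s] for s in seeds)
            for a in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(masses, masses[1:]))

    def test_symmetric_normalization_also_sums_to_one(self):
        g = nx.barabasi_albert_graph(20, 2, seed=2)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        res = random_walk_restart(g, sorted(g.nodes)[:3], normalization="symmetric")
        assert sum(res.scores.values()) == pytest.approx(1.0, abs=1e-9)

    def test_errors(self):
        g = nx.Graph([("A", "B")])
        with pytest.raises(ValidationError, match="no seed"):
            random_walk_restart(g, ["ZZZ"])
        with pytest.raises(ValidationError, match="alpha"):
            random_walk_restart(g, ["A"], alpha=0.0)


class TestModule:
    def test_restart_only_module_is_subset_of_seeds(self):
        g = nx.barabasi_albert_graph(30, 2, seed=4)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        seeds = ("N01", "N02", "N05")
        prop = random_walk_restart(g, seeds, alpha=1.0)
        module = identify_module(prop, g, k=3)
        assert set(module) <= set(seeds)

    def test_k_at_least_graph_size_returns_all_nodes(self):
        g = nx.path_graph(5)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        prop = random_walk_restart(g, ["N0"], alpha=0.5)
        with pytest.warns(UserWarning, match="clamped"):
            module = identify_module(prop, g, k=10)
        assert set(module) == set(g.nodes)

    def test_star_graph_ties_break_lexicographically(self):
        g = nx.Graph([("HUB", leaf) for leaf in ("L1", "L2", "L3", "L4", "L5")])
        prop = random_walk_restart(g, ["HUB"], alpha=0.5)
        # all leaves tie by symmetry; top-3 = hub + two lexicographically first
        module = identify_module(prop, g, k=3)
        assert set(module) == {"HUB", "L1", "L2"}


class TestAnnotation:
    @staticmethod
    def _net():
        g = nx.Graph([("GSK3B", "LINKER"), ("LINKER", "BDNF")])
        return shortest_path_induction(g, ["GSK3B", "BDNF"])

    def test_connector_gets_null_and_seeds_get_fc(self):
        fc = pd.DataFrame(
            {"fc": [0.5, 0.7, 0.9, -1.0]},
            index=pd.Index(["GSK3β", "phospho-GSK3β", "phospho-GSK3α/β", "BDNF"],
                           name="analyte"),
        )
        net = annotate_with_fc(self._net(), fc, default_mapping())
        assert net.fc["LINKER"] is None
        assert net.fc["BDNF"] == pytest.approx(-1.0)  # single source analyte
        assert net.fc["GSK3B"] == pytest.approx(np.mean([0.5, 0.7, 0.9]))  # collapse mean

    def test_missing_fold_change_rejected(self):
        fc = pd.DataFrame({"fc": [0.5]}, index=pd.Index(["GSK3β"], name="analyte"))
        with pytest.raises(ValidationError, match="no fold change"):
            annotate_with_fc(self._net(), fc, default_mapping())


class TestPathwaySubnetwork:
    @staticmethod
    def _net():
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D"), ("A", "D"), ("D", "E")])
        return shortest_path_induction(g, ["A", "C", "E"])

    def test_pathway_superset_returns_whole_network(self):
        net = self._net()
        sub = extract_pathway_subnetwork(net, set(net.nodes()) | {"EXTRA"})
        assert sub.nodes() == net.nodes()

    def test_disjoint_pathway_returns_empty_with_warning(self):
        with pytest.warns(UserWarning, match="no genes"):
            sub = extract_pathway_subnetwork(self._net(), {"X", "Y"})
        assert sub.graph.number_of_nodes() == 0

    def test_connector_on_path_between_pathway_genes_kept(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        net = shortest_path_induction(g, ["A", "C"])  # B is a connector
        sub = extract_pathway_subnetwork(net, {"A", "C"})
        assert set(sub.nodes()) == {"A", "B", "C"}
        assert sub.roles["B"] == "connector"

    def test_relabeling_equivariance(self):
        g = nx.gnp_random_graph(15, 0.25, seed=9)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        seeds = sorted(g.nodes)[:4]
        net = shortest_path_induction(g, seeds)
        relabel = {n: f"X{n}" for n in g.nodes}
        g2 = nx.relabel_nodes(g, relabel)
        net2 = shortest_path_induction(g2, [relabel[s] for s in seeds])
        assert set(net2.nodes()) == {relabel[n] for n in net.nodes()}
        prop = random_walk_restart(g, seeds, alpha=0.3)
        prop2 = random_walk_restart(g2, [relabel[s] for s in seeds], alpha=0.3)
        for node, score in prop.scores.items():
            assert prop2.scores[relabel[node]] == pytest.approx(score, abs=1e-10)
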