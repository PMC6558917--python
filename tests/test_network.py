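"""Enzyme graphs, random-walk flows, map equation, community detection."""

import math

import networkx as nx
import numpy as np
import pytest

from ovoflow.model import MetabolicModel, Metabolite, Reaction, parse_gpr
from ovoflow.network import (
    build_enzyme_network,
    detect_communities,
    map_equation_codelength,
    node_flows,
)
from ovoflow.synth import GeneratorSpec, planted_partition_graph, random_consistent_model

from .helpers import codelength_oracle, optimal_codelength


def two_gene_model() -> MetabolicModel:
    mets = [Metabolite("A_c"), Metabolite("B_c")]
    rxns = [
        Reaction("R1", {"A_c": -1, "B_c": 1}, 0, 10, gene_sets=parse_gpr("g1")),
        Reaction("R2", {"A_c": -1, "B_c": 1}, 0, 10, gene_sets=parse_gpr("g2")),
    ]
    return MetabolicModel(mets, rxns)


def weighted(graph: nx.Graph) -> nx.Graph:
    for _, _, d in graph.edges(data=True):
        d.setdefault("weight", 1)
    return graph


class TestBuildNetwork:
    def test_shared_metabolites_give_projection_weight(self):
        net = build_enzyme_network(two_gene_model())
        assert net.bipartite["g1"] == frozenset({"A_c", "B_c"})
        assert net.w == {"g1": 2, "g2": 2}
        assert net.projection.edges["g1", "g2"]["weight"] == 2

    def test_currency_exclusion_empties_projection(self):
        net = build_enzyme_network(two_gene_model(), currency_exclusions={"A_c", "B_c"})
        assert net.projection.number_of_edges() == 0
        assert set(net.enzymes) == {"g1", "g2"}

    def test_exchanges_excluded_by_default(self):
        mets = [Metabolite("A_c")]
        rxns = [Reaction("EX_A", {"A_c": -1}, -10, 0, gene_sets=parse_gpr("g1"))]
        with pytest.raises(ValueError, match="no enzymes"):
            build_enzyme_network(MetabolicModel(mets, rxns))

    def test_bipartite_degrees_match_hand_count(self):
        res = random_consistent_model(GeneratorSpec(seed=5, n_reactions=15))
        net = build_enzyme_network(res.model)
        for gene, mets in net.bipartite.items():
            by_hand = set()
            for r in res.model.reactions:
                if r.is_exchange or gene not in r.genes:
                    continue
                by_hand |= set(r.metabolites)
            assert mets == by_hand
            assert net.w[gene] == len(by_hand)


class TestNodeFlows:
    def test_ring_is_uniform_at_damping_one(self):
        f = node_flows(weighted(nx.cycle_graph(4)), damping=1.0)
        assert all(v == pytest.approx(0.25, abs=1e-9) for v in f.f.values())

    def test_path_flows_are_degree_proportional(self):
        f = node_flows(weighted(nx.path_graph(3)), damping=1.0)
        assert [f.f[i] for i in range(3)] == pytest.approx([0.25, 0.5, 0.25], abs=1e-9)

    def test_damped_flows_match_dense_eigenvector(self):
        g = weighted(nx.path_graph(3))
        f = node_flows(g, damping=0.85)
        # dense oracle: stationary vector of the explicit transition matrix
        W = nx.to_numpy_array(g, nodelist=[0, 1, 2])
        P = 0.85 * W / W.sum(axis=1, keepdims=True) + 0.15 / 3
        vals, vecs = np.linalg.eig(P.T)
        stat = np.real(vecs[:, np.argmax(np.real(vals))])
        stat = stat / stat.sum()
        assert [f.f[i] for i in range(3)] == pytest.approx(list(stat), abs=1e-8)

    def test_flows_sum_to_one_and_are_nonnegative(self):
        g, _ = planted_partition_graph(GeneratorSpec(seed=2))
        f = node_flows(g, damping=0.85)
        assert sum(f.f.values()) == pytest.approx(1.0, abs=1e-9)
        assert min(f.f.values()) >= 0

    def test_edgeless_graph_is_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1])
        with pytest.raises(ValueError, match="no edges"):
            node_flows(g)


class TestMapEquation:
    def test_single_module_reduces_to_flow_entropy(self):
        g = weighted(nx.cycle_graph(4))
        f = node_flows(g, damping=1.0)
        L = map_equation_codelength(g, f, {i: 0 for i in range(4)})
        assert L == pytest.approx(2.0, abs=1e-9)

    def test_disconnected_cliques_have_zero_exit_term(self):
        g = weighted(nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4)))
        f = node_flows(g, damping=1.0)
        L = map_equation_codelength(g, f, {i: i // 4 for i in range(8)})
        # two modules, each coding 4 equal-flow nodes: 2 bits, no exit events
        assert L == pytest.approx(2.0, abs=1e-9)

    @pytest.mark.parametrize("damping", [1.0, 0.85])
    def test_matches_independent_formula_on_random_graph(self, damping):
        rng = np.random.default_rng(7)
        g = weighted(nx.gnp_random_graph(6, 0.6, seed=4))
        f = node_flows(g, damping=damping)
        for _ in range(5):
            assign = {v: int(rng.integers(0, 3)) for v in g.nodes}
            mine = map_equation_codelength(g, f, assign)
            oracle = codelength_oracle(g, f.f, damping, assign)
            assert mine == pytest.approx(oracle, abs=1e-12)

    def test_missing_node_raises(self):
        g = weighted(nx.path_graph(3))
        f = node_flows(g, damping=1.0)
        with pytest.raises(KeyError):
            map_equation_codelength(g, f, {0: 0, 1: 0})


class TestDetectCommunities:
    def test_two_cliques_joined_by_edge_are_recovered(self):
        g = weighted(nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4)))
        g.add_edge(3, 4, weight=1)
        part = detect_communities(g, n_iterations=50, seed=0)
        groups = {}
        for v, c in part.assignment.items():
            groups.setdefault(c, set()).add(v)
        assert sorted(map(sorted, groups.values())) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_single_clique_is_one_community(self):
        g = weighted(nx.complete_graph(5))
        part = detect_communities(g, n_iterations=20, seed=0)
        assert part.n_communities == 1

    def test_codelength_never_worse_than_trivial_partition(self):
        g, _ = planted_partition_graph(GeneratorSpec(seed=8))
        f = node_flows(g, damping=1.0)
        part = detect_communities(g, flows=f, n_iterations=20, seed=1)
        trivial = map_equation_codelength(g, f, {v: 0 for v in g.nodes})
        assert part.codelength <= trivial + 1e-12

    def test_matches_exhaustive_optimum_on_small_graphs(self):
        for seed, n in [(0, 5), (1, 6), (2, 7)]:
            g = weighted(nx.gnp_random_graph(n, 0.5, seed=seed))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() == 0:
                continue
            f = node_flows(g, damping=1.0)
            part = detect_communities(g, flows=f, n_iterations=100, seed=3)
            best = optimal_codelength(g, f.f, 1.0)
            assert part.codelength == pytest.approx(best, abs=1e-9)

    def test_planted_partition_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        g, labels = planted_partition_graph(GeneratorSpec(seed=11))
        part = detect_communities(g, n_iterations=30, seed=5)
        nodes = sorted(g.nodes)
        ari = adjusted_rand_score(
            [labels[v] for v in nodes], [part.assignment[v] for v in nodes]
        )
        assert ari >= 0.9

    def test_reproducible_given_seed(self):
        g, _ = planted_partition_graph(GeneratorSpec(seed=4))
        a = detect_communities(g, n_iterations=10, seed=9)
        b = detect_communities(g, n_iterations=10, seed=9)
        assert a.assignment == b.assignment
        assert a.codelength == b.codelength


class TestExports:
    def test_edge_list_and_pajek_round_out_projection(self, tmp_path):
        from ovoflow.network import write_edge_list, write_pajek

        net = build_enzyme_network(two_gene_model())
        write_edge_list(net, tmp_path / "edges.tsv")
        lines = (tmp_path / "edges.tsv").read_text().strip().splitlines()
        assert lines[0] == "source\ttarget\tweight"
        assert lines[1] == "g1\tg2\t2"
        write_pajek(net, tmp_path / "net.net")
        content = (tmp_path / "net.net").read_text()
        assert "*Vertices 2" in content and "*Edges" in content
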