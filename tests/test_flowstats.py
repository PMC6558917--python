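"""Normalized flow, permutation nulls, Z-scores, entity ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ovoflow.flowstats import (
    IntensityVector,
    normalized_flow,
    permutation_null,
    score_genes,
    score_metabolites,
    score_pathways,
    top_entities,
    zscore,
)
from ovoflow.network import build_enzyme_network, detect_communities, node_flows
from ovoflow.synth import GeneratorSpec, random_consistent_model


class TestNormalizedFlow:
    def test_single_member_identity(self):
        assert normalized_flow(["a"], {"a": 1}, {"a": 1.0}, {"a": 1.0}) == 1.0

    def test_hand_substitution_two_members(self):
        val = normalized_flow(
            ["a", "b"], {"a": 2, "b": 2}, {"a": 1.0, "b": 1.0}, {"a": 0.3, "b": 0.1}
        )
        assert val == pytest.approx(0.4, abs=1e-12)

    def test_zero_intensity_kills_numerator(self):
        assert normalized_flow(
            ["a", "b"], {"a": 2, "b": 3}, {"a": 0.0, "b": 0.0}, {"a": 0.5, "b": 0.5}
        ) == 0.0

    def test_empty_member_set_is_zero(self):
        assert normalized_flow([], {}, {}, {}) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalized_flow(["a"], {"a": -1}, {"a": 1.0}, {"a": 0.1})

    def test_homogeneity_in_intensity_and_weights(self):
        members = ["a", "b", "c"]
        w = {"a": 1.0, "b": 2.0, "c": 3.0}
        I = {"a": 0.5, "b": 1.5, "c": 2.0}
        f = {"a": 0.2, "b": 0.3, "c": 0.5}
        base = normalized_flow(members, w, I, f)
        scaled_I = normalized_flow(members, w, {k: 7 * v for k, v in I.items()}, f)
        assert scaled_I == pytest.approx(7 * base, rel=1e-12)
        scaled_w = normalized_flow(members, {k: 4 * v for k, v in w.items()}, I, f)
        assert scaled_w == pytest.approx(2 * base, rel=1e-12)  # sqrt(4) = 2


class TestPermutationNull:
    def test_degenerate_pool_has_zero_sd(self):
        mu, sigma = permutation_null([(1.0, 1.0, 0.2)] * 6, 3, n_perm=50, seed=0)
        assert sigma == pytest.approx(0.0, abs=1e-12)
        assert mu == pytest.approx(3 * 0.2 / math.sqrt(3), abs=1e-12)

    def test_full_pool_sample_is_constant(self):
        pool = [(1.0, float(i), 0.1 * i) for i in range(1, 5)]
        mu, sigma = permutation_null(pool, size=len(pool), n_perm=20, seed=1)
        assert sigma == pytest.approx(0.0, abs=1e-12)

    def test_oversized_sample_raises(self):
        with pytest.raises(ValueError):
            permutation_null([(1, 1, 1)] * 3, 4)

    def test_seed_reproducibility_bitwise(self):
        pool = [(float(i % 3 + 1), float(i), 0.01 * i) for i in range(30)]
        assert permutation_null(pool, 5, 100, seed=7) == permutation_null(pool, 5, 100, seed=7)

    def test_mean_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        pool = [
            (float(rng.integers(1, 4)), float(rng.uniform(0.5, 2)), float(rng.uniform(0, 0.2)))
            for _ in range(20)
        ]
        size = 5
        w = np.array([p[0] for p in pool])
        wif = np.array([p[0] * p[1] * p[2] for p in pool])
        exact_vals = [
            wif[list(c)].sum() / math.sqrt(w[list(c)].sum())
            for c in itertools.combinations(range(20), size)
        ]
        exact_mu = float(np.mean(exact_vals))
        exact_sd = float(np.std(exact_vals))
        mu, _ = permutation_null(pool, size, n_perm=10000, seed=5)
        mc_se = exact_sd / math.sqrt(10000)
        assert abs(mu - exact_mu) <= 3 * mc_se


class TestZscore:
    def test_centre_is_zero(self):
        assert zscore(1.5, 1.5, 2.0) == (0.0, True)

    def test_two_sigma(self):
        z, ok = zscore(3.0, 1.0, 1.0)
        assert ok and z == pytest.approx(2.0)

    def test_degenerate_sigma_flags_undefined(self):
        z, ok = zscore(1.0, 0.0, 0.0)
        assert not ok and math.isnan(z)


@pytest.fixture(scope="module")
def scored_fixture():
    res = random_consistent_model(GeneratorSpec(seed=9, n_reactions=30))
    net = build_enzyme_network(res.model)
    flows = node_flows(net, damping=1.0)
    part = detect_communities(net, flows=flows, n_iterations=20, seed=9)
    return res.model, net, flows, part


class TestEntityScores:
    def test_identical_genes_get_identical_z(self, scored_fixture):
        _, net, flows, _ = scored_fixture
        table = score_genes(net, flows, n_perm=100, seed=1)
        # genes with equal (w, I, f) triples must tie exactly
        key = table.set_index("entity")[["f_p", "z"]]
        w = net.w
        for a in net.enzymes:
            for b in net.enzymes:
                if a < b and w[a] == w[b] and flows.f[a] == flows.f[b]:
                    assert key.loc[a, "z"] == key.loc[b, "z"]

    def test_highest_wif_gene_ranks_first(self, scored_fixture):
        _, net, flows, _ = scored_fixture
        rng = np.random.default_rng(2)
        I = IntensityVector({g: float(rng.uniform(0.5, 2)) for g in net.enzymes})
        table = score_genes(net, flows, I, n_perm=200, seed=2)
        best = max(net.enzymes, key=lambda g: net.w[g] * I.get(g) * flows.f[g] / math.sqrt(net.w[g]) if net.w[g] else 0.0)
        assert top_entities(table, 1).iloc[0]["entity"] == best

    def test_planted_hot_pathway_tops_z(self, scored_fixture):
        model, net, flows, part = scored_fixture
        from ovoflow.flowstats import gene_pathways

        gp = gene_pathways(model, net)
        hot = sorted({pw for pws in gp.values() for pw in pws})[0]
        I = IntensityVector(
            {g: (10.0 if hot in gp.get(g, ()) else 1.0) for g in net.enzymes}
        )
        table = score_pathways(net, flows, part, gp, I, n_perm=500, seed=9)
        grouped = table.groupby("entity")["z"].max()
        assert grouped.idxmax() == hot

    def test_metabolite_f_p_equals_flow_of_single_enzyme(self, scored_fixture):
        _, net, flows, _ = scored_fixture
        table = score_metabolites(net, flows, n_perm=100, seed=3)
        single = [
            m for m in net.metabolite_nodes if len(net.enzymes_of_metabolite(m)) == 1
        ]
        for met in single[:5]:
            (enz,) = net.enzymes_of_metabolite(met)
            row = table[table["entity"] == met].iloc[0]
            assert row["f_p"] == pytest.approx(flows.f[enz], rel=1e-12)

    def test_hub_metabolite_outranks_leaf_with_equal_flows(self):
        # numerator grows linearly in member count, denominator as sqrt(n)
        f = {f"e{i}": 0.1 for i in range(6)}
        w = {k: 1.0 for k in f}
        hub = normalized_flow(list(f), w, {k: 1.0 for k in f}, f)
        leaf = normalized_flow(["e0"], w, {"e0": 1.0}, f)
        assert hub > leaf


class TestTopEntities:
    def test_short_table_returns_all_in_z_order(self):
        t = pd.DataFrame(
            {"entity": ["a", "b", "c"], "f_p": [1, 2, 3], "z": [0.5, 2.0, 1.0]}
        )
        out = top_entities(t, k=10)
        assert list(out["entity"]) == ["b", "c", "a"]
        assert list(out["rank"]) == [1, 2, 3]

    def test_tie_broken_by_f_p(self):
        t = pd.DataFrame(
            {"entity": ["a", "b"], "f_p": [1.0, 5.0], "z": [1.0, 1.0]}
        )
        assert list(top_entities(t, 2)["entity"]) == ["b", "a"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(
            {
                "entity": [f"e{i}" for i in range(25)],
                "f_p": rng.uniform(0, 5, 25),
                "z": rng.normal(0, 1, 25).round(1),  # force some ties
            }
        )
        out = top_entities(t, 10)
        oracle = sorted(
            t.itertuples(), key=lambda r: (-r.z, -r.f_p, r.entity)
        )[:10]
        assert list(out["entity"]) == [r.entity for r in oracle]

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            top_entities(pd.DataFrame(columns=["entity", "f_p", "z"]))
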