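"""Flux variability, blocked-reaction detection, FASTCORE extraction."""

import numpy as np
import pandas as pd
import pytest

from ovoflow.consistency import (
    CoreSet,
    ExpressionRule,
    FastcoreError,
    expression_core,
    fastcore,
    find_blocked,
    flux_variability,
)
from ovoflow.model import MetabolicModel, Metabolite, Reaction, evaluate_gpr
from ovoflow.synth import GeneratorSpec, random_consistent_model

from .conftest import make_chain, make_diamond
from .helpers import blocked_oracle, min_extra_reactions


class TestFluxVariability:
    def test_chain_middle_reaction_spans_uptake_capacity(self, chain_model):
        fva = flux_variability(chain_model)
        assert fva.loc["AB", "minimum"] == pytest.approx(0.0, abs=1e-9)
        assert fva.loc["AB", "maximum"] == pytest.approx(10.0)

    def test_unconsumed_product_forces_zero_range(self):
        m = MetabolicModel(
            [Metabolite("A_c"), Metabolite("C_c")],
            [
                Reaction("EX_A", {"A_c": -1}, -10, 0),
                Reaction("AC", {"A_c": -1, "C_c": 1}, 0, 1000),
            ],
        )
        fva = flux_variability(m, ["AC"])
        assert fva.loc["AC", "minimum"] == pytest.approx(0.0, abs=1e-9)
        assert fva.loc["AC", "maximum"] == pytest.approx(0.0, abs=1e-9)

    def test_isolated_reversible_loop_allows_circulation(self):
        m = MetabolicModel(
            [Metabolite("A_c"), Metabolite("B_c")],
            [
                Reaction("AB", {"A_c": -1, "B_c": 1}, -50, 50),
                Reaction("BA", {"B_c": -1, "A_c": 1}, -50, 50),
            ],
        )
        fva = flux_variability(m)
        for rid in ("AB", "BA"):
            assert fva.loc[rid, "minimum"] == pytest.approx(-50.0)
            assert fva.loc[rid, "maximum"] == pytest.approx(50.0)


class TestFindBlocked:
    def test_orphan_branch_is_blocked(self):
        m = make_chain()
        rxns = list(m.reactions) + [Reaction("AC", {"A_c": -1, "C_c": 1}, 0, 1000)]
        mets = list(m.metabolites) + [Metabolite("C_c")]
        m2 = MetabolicModel(mets, rxns)
        report = find_blocked(m2)
        assert report.blocked_reactions == frozenset({"AC"})
        assert "C_c" in report.dead_end_metabolites

    def test_connected_chain_has_no_blocked_reactions(self, chain_model):
        assert find_blocked(chain_model).blocked_reactions == frozenset()

    def test_deleting_export_blocks_everything_upstream(self, chain_model):
        m = chain_model.subset(["EX_A", "AB"])
        report = find_blocked(m)
        assert report.blocked_reactions == frozenset({"EX_A", "AB"})

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_two_lp_oracle_on_random_models(self, seed):
        res = random_consistent_model(
            GeneratorSpec(seed=seed, n_reactions=25, n_orphans=seed % 4)
        )
        assert find_blocked(res.model).blocked_reactions == blocked_oracle(res.model)


class TestFastcore:
    def test_chain_core_pulls_in_whole_path(self, chain_model):
        sub = fastcore(chain_model, CoreSet(frozenset({"AB"})))
        assert {r.id for r in sub.reactions} == {"EX_A", "AB", "EX_B"}

    def test_empty_core_gives_empty_submodel(self, chain_model):
        sub = fastcore(chain_model, CoreSet(frozenset()))
        assert len(sub.reactions) == 0

    def test_diamond_keeps_exactly_one_route(self, diamond_model):
        sub = fastcore(diamond_model, CoreSet(frozenset({"EX_A", "EX_B"})))
        ids = {r.id for r in sub.reactions}
        assert len(ids) == 3
        assert len(ids & {"AB1", "AB2"}) == 1

    def test_blocked_core_reaction_raises_listing_ids(self, chain_model):
        rxns = list(chain_model.reactions) + [
            Reaction("AC", {"A_c": -1, "C_c": 1}, 0, 1000)
        ]
        mets = list(chain_model.metabolites) + [Metabolite("C_c")]
        m = MetabolicModel(mets, rxns)
        with pytest.raises(FastcoreError) as err:
            fastcore(m, CoreSet(frozenset({"AC"})))
        assert "AC" in err.value.reaction_ids

    @pytest.mark.parametrize("seed", range(10))
    def test_output_is_consistent_and_contains_core(self, seed):
        res = random_consistent_model(GeneratorSpec(seed=seed, n_reactions=20))
        rng = np.random.default_rng(seed)
        rids = [r.id for r in res.model.reactions]
        core = set(rng.choice(rids, size=4, replace=False))
        sub = fastcore(res.model, CoreSet(frozenset(core)))
        ids = {r.id for r in sub.reactions}
        assert core <= ids
        assert find_blocked(sub).blocked_reactions == frozenset()

    @pytest.mark.parametrize("seed", range(10))
    def test_noncore_count_matches_enumeration_minimum(self, seed):
        res = random_consistent_model(GeneratorSpec(seed=100 + seed, n_reactions=11))
        rng = np.random.default_rng(seed)
        rids = [r.id for r in res.model.reactions]
        core = set(rng.choice(rids, size=3, replace=False))
        sub = fastcore(res.model, CoreSet(frozenset(core)))
        extra = len(sub.reactions) - len(core)
        assert extra >= min_extra_reactions(res.model, core)

    def test_reversible_representation_does_not_change_result(self):
        """A reversible reaction flipped in sign yields the same extraction."""
        mets = [Metabolite("A_c"), Metabolite("B_c")]
        fwd = MetabolicModel(
            mets,
            [
                Reaction("EX_A", {"A_c": -1}, -10, 0),
                Reaction("AB", {"A_c": -1, "B_c": 1}, -1000, 1000),
                Reaction("EX_B", {"B_c": -1}, 0, 1000),
            ],
        )
        flipped = MetabolicModel(
            mets,
            [
                Reaction("EX_A", {"A_c": -1}, -10, 0),
                Reaction("AB", {"A_c": 1, "B_c": -1}, -1000, 1000),
                Reaction("EX_B", {"B_c": -1}, 0, 1000),
            ],
        )
        a = {r.id for r in fastcore(fwd, CoreSet(frozenset({"AB"}))).reactions}
        b = {r.id for r in fastcore(flipped, CoreSet(frozenset({"AB"}))).reactions}
        assert a == b == {"EX_A", "AB", "EX_B"}


class TestExpressionCore:
    def _model(self):
        mets = [Metabolite("A_c"), Metabolite("B_c"), Metabolite("C_c")]
        rxns = [
            Reaction("EX_A", {"A_c": -1}, -10, 0),
            Reaction("R_or", {"A_c": -1, "B_c": 1}, 0, 10,
                     gene_sets=(frozenset({"g1"}), frozenset({"g2"}))),
            Reaction("R_and", {"B_c": -1, "C_c": 1}, 0, 10,
                     gene_sets=(frozenset({"g1", "g2"}),)),
            Reaction("EX_C", {"C_c": -1}, 0, 1000),
        ]
        return MetabolicModel(mets, rxns)

    def test_disjunction_needs_any_gene(self):
        m = self._model()
        table = pd.DataFrame(
            {"gene": ["g1", "g2"], "intensity": [1.0, 9.0], "detected": [False, True]}
        )
        core = expression_core(m, table)
        assert "R_or" in core.reaction_ids
        assert "R_and" not in core.reaction_ids  # conjunction needs both

    def test_quantile_rule_without_detection_flag(self):
        m = self._model()
        table = pd.DataFrame({"gene": ["g1", "g2"], "intensity": [1.0, 9.0]})
        core = expression_core(m, table, ExpressionRule(quantile=0.5))
        # only g2 exceeds the median
        assert core.reaction_ids == frozenset({"R_or"})

    def test_zero_gene_overlap_raises(self):
        m = self._model()
        table = pd.DataFrame({"gene": ["x1"], "intensity": [5.0], "detected": [True]})
        with pytest.raises(ValueError, match="overlap"):
            expression_core(m, table)

    def test_core_matches_direct_rule_application(self):
        res = random_consistent_model(GeneratorSpec(seed=3, n_reactions=20))
        model = res.model
        genes = sorted(model.genes)
        rng = np.random.default_rng(3)
        expressed = set(rng.choice(genes, size=int(0.4 * len(genes)), replace=False))
        table = pd.DataFrame(
            {"gene": genes, "intensity": 1.0, "detected": [g in expressed for g in genes]}
        )
        core = expression_core(model, table)
        by_hand = {
            r.id
            for r in model.reactions
            if r.gene_sets and evaluate_gpr(r.gene_sets, expressed)
        }
        assert core.reaction_ids == frozenset(by_hand)


class TestFvaFractionOfOptimum:
    def test_optimum_constraint_narrows_ranges(self, diamond_model):
        free = flux_variability(diamond_model, ["AB1", "AB2"])
        constrained = flux_variability(
            diamond_model, ["AB1", "AB2"],
            objective={"EX_B": 1.0}, fraction_of_optimum=1.0,
        )
        # at full optimum the two routes must jointly carry 10
        assert constrained.loc["AB1", "minimum"] == pytest.approx(0.0, abs=1e-8)
        assert constrained.loc["AB1", "maximum"] == pytest.approx(10.0)
        total_min = (
            constrained.loc["AB1", "minimum"] + constrained.loc["AB2", "minimum"]
        )
        assert free.loc["AB1", "minimum"] == pytest.approx(0.0, abs=1e-8)
        assert total_min == pytest.approx(0.0, abs=1e-8)
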