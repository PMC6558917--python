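"""Stage-specific FBA, exchange classification, somatic-oocyte coupling."""

import numpy as np
import pandas as pd
import pytest

from ovoflow.coupled import (
    StageConfig,
    classify_exchanges,
    couple_cells,
    run_stage_panel,
    solve_fba,
)
from ovoflow.model import apply_medium


def primary_config(**kwargs) -> StageConfig:
    defaults = dict(
        stage="primary",
        somatic_objective={"EX_pyr_e": 1.0},
        oocyte_objective={"BIOMASS_OOC": 1.0, "EX_pyr_e": -1.0},
        pyruvate_exchange="EX_pyr_e",
        oxygen_exchange="EX_o2_e",
    )
    defaults.update(kwargs)
    return StageConfig(**defaults)


class TestSolveFBA:
    def test_chain_export_maximum_equals_uptake_cap(self, chain_model):
        res = solve_fba(chain_model, {"EX_B": 1.0})
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(10.0)

    def test_closed_exchanges_force_zero_production(self, toy_models):
        somatic, _, _ = toy_models
        closed = apply_medium(somatic, {})
        res = solve_fba(closed, {"EX_pyr_e": 1.0})
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_cobra_on_toy_model(self, toy_models, tmp_path):
        cobra = pytest.importorskip("cobra")
        from ovoflow.model import write_model

        somatic, _, _ = toy_models
        write_model(somatic, tmp_path / "m.xml", format="sbml")
        cm = cobra.io.read_sbml_model(str(tmp_path / "m.xml"))
        for objective in ("EX_pyr_e", "EX_lac_e", "BIOMASS_SOM"):
            cm.objective = objective
            theirs = cm.optimize().objective_value
            mine = solve_fba(somatic, {objective: 1.0}).objective_value
            assert mine == pytest.approx(theirs, abs=1e-6)

    def test_mass_balance_at_optimum(self, toy_models):
        somatic, _, _ = toy_models
        res = solve_fba(somatic, {"EX_pyr_e": 1.0, "BIOMASS_SOM": 1.0})
        v = np.array([res.fluxes[r.id] for r in somatic.reactions])
        assert np.abs(somatic.S @ v).max() <= 1e-8

    def test_empty_objective_rejected(self, chain_model):
        with pytest.raises(ValueError):
            solve_fba(chain_model, {})


class TestClassifyExchanges:
    def test_sign_conventions(self, toy_models):
        somatic, _, _ = toy_models
        res = solve_fba(somatic, {"EX_pyr_e": 1.0})
        table = classify_exchanges(somatic, res, "somatic").set_index("metabolite")
        assert table.at["pyr_e", "direction"] == "secreted"
        assert table.at["glc_e", "direction"] == "consumed"

    def test_tolerance_band_drops_tiny_fluxes(self, toy_models):
        somatic, _, _ = toy_models
        res = solve_fba(somatic, {"EX_pyr_e": 1.0})
        res.fluxes["EX_lac_e"] = 1e-9
        table = classify_exchanges(somatic, res)
        assert "lac_e" not in set(table["metabolite"])

    def test_non_optimal_result_rejected(self, toy_models):
        somatic, _, _ = toy_models
        from ovoflow.coupled import FluxResult

        with pytest.raises(ValueError):
            classify_exchanges(somatic, FluxResult({}, float("nan"), "infeasible"))


class TestCoupling:
    def test_oocyte_availability_is_plasma_plus_scaled_secretion(self, toy_models):
        somatic, oocyte, plasma = toy_models
        r = couple_cells(
            somatic, oocyte, primary_config(), cell_ratio=50.0, plasma=plasma,
            pyruvate_target=2.0,
        )
        assert r.converged
        secreted = r.somatic.fluxes["EX_pyr_e"]
        assert r.oocyte_medium["pyr_e"] == pytest.approx(
            plasma["pyr_e"] + 50.0 * secreted, rel=1e-6
        )
        assert r.oocyte_medium["pyr_e"] == pytest.approx(100.0, rel=1e-4)

    def test_zero_cell_ratio_decouples_exactly(self, toy_models):
        somatic, oocyte, plasma = toy_models
        r = couple_cells(
            somatic, oocyte, primary_config(), cell_ratio=0.0, plasma=plasma
        )
        assert r.oocyte_medium == {m: max(u, 0.0) for m, u in plasma.items()}
        stand_alone = solve_fba(
            apply_medium(oocyte, plasma),
            {"BIOMASS_OOC": 1.0, "EX_pyr_e": -1.0},
        )
        assert r.oocyte.objective_value == pytest.approx(
            stand_alone.objective_value, rel=1e-9
        )

    def test_target_at_unconstrained_optimum_converges_first_step(self, toy_models):
        somatic, oocyte, plasma = toy_models
        free = couple_cells(
            somatic, oocyte, primary_config(), 10.0, plasma, pyruvate_target=None
        )
        opt = free.somatic.fluxes["EX_pyr_e"]
        r = couple_cells(
            somatic, oocyte, primary_config(), 10.0, plasma, pyruvate_target=opt
        )
        assert r.converged and r.n_iterations == 1
        assert r.residual <= 1e-6

    def test_bisection_converges_within_iteration_cap(self, toy_models):
        somatic, oocyte, plasma = toy_models
        r = couple_cells(
            somatic, oocyte, primary_config(), 25.0, plasma,
            pyruvate_target=3.7, tol=1e-6, max_iter=50,
        )
        assert r.converged and r.n_iterations <= 50
        assert abs(r.somatic.fluxes["EX_pyr_e"] - 3.7) <= 1e-6

    def test_mass_balance_of_both_solutions(self, toy_models):
        somatic, oocyte, plasma = toy_models
        r = couple_cells(somatic, oocyte, primary_config(), 50.0, plasma, 2.0)
        for model, res in ((somatic, r.somatic), (oocyte, r.oocyte)):
            v = np.array([res.fluxes[rx.id] for rx in model.reactions])
            assert np.abs(model.S @ v).max() <= 1e-8

    def test_enlarging_medium_never_hurts_oocyte(self, toy_models):
        somatic, oocyte, plasma = toy_models
        cfg = primary_config()
        small = solve_fba(apply_medium(oocyte, {"pyr_e": 5.0, "o2_e": 10.0}),
                          cfg.oocyte_objective)
        large = solve_fba(apply_medium(oocyte, {"pyr_e": 50.0, "o2_e": 20.0}),
                          cfg.oocyte_objective)
        assert large.objective_value >= small.objective_value - 1e-9

    def test_oxygen_restricted_to_uptake_for_somatic(self, toy_models):
        somatic, oocyte, plasma = toy_models
        r = couple_cells(somatic, oocyte, primary_config(), 10.0, plasma, None)
        assert r.somatic.fluxes["EX_o2_e"] <= 1e-9


class TestStagePanel:
    def _configs(self):
        return [
            primary_config(),
            primary_config(
                stage="large_antral",
                somatic_objective={"EX_pyr_e": 1.0, "EX_lac_e": 0.5},
            ),
        ]

    def test_one_result_per_stage_with_stage_objectives(self, toy_models):
        somatic, oocyte, plasma = toy_models
        results = run_stage_panel(
            somatic, oocyte, self._configs(),
            {"primary": 20.0, "large_antral": 400.0}, plasma,
        )
        assert [r.stage for r in results] == ["primary", "large_antral"]
        # the antral objective rewards lactate export; the primary one does not
        assert results[1].somatic.fluxes["EX_lac_e"] >= results[0].somatic.fluxes["EX_lac_e"] - 1e-9

    def test_missing_cell_count_raises(self, toy_models):
        somatic, oocyte, plasma = toy_models
        with pytest.raises(KeyError):
            run_stage_panel(somatic, oocyte, self._configs(), {"primary": 1.0}, plasma)

    def test_exchange_table_matches_hand_solution(self, toy_models):
        somatic, oocyte, plasma = toy_models
        r = couple_cells(somatic, oocyte, primary_config(), 50.0, plasma, 2.0)
        som = r.exchanged[r.exchanged.cell_type == "somatic"].set_index("metabolite")
        # 2 pyruvate require 1 glucose; target flux hand-checkable
        assert som.at["pyr_e", "direction"] == "secreted"
        assert som.at["pyr_e", "flux"] == pytest.approx(2.0, abs=1e-5)
        assert som.at["glc_e", "flux"] == pytest.approx(-1.0, abs=1e-5)
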