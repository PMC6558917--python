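"""Stage-specific FBA and iterative somatic-oocyte metabolic coupling.

Within a follicle the somatic layers (granulosa/theca, later cumulus and
mural) sit between plasma and the oocyte.  The coupling scheme solves the
somatic cell's FBA first (objective: pyruvate + biomass production plus
stage-dependent terms, subject to measured exchange constraints), scales
its net exchange fluxes by the number of somatic cells per oocyte, and
adds/subtracts them from the plasma supply to form the oocyte's medium.
The oocyte then maximises biomass production plus pyruvate consumption.

The somatic uptake allowance is a single scalar multiplier on the plasma
medium, adjusted by bisection until the somatic pyruvate secretion matches
the experimentally measured target.

Sign convention: exchange flux > 0 is secretion, < 0 is uptake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lp import LPResult, solve_lp
from .model import MetabolicModel, ModelError, apply_medium

__all__ = [
    "StageConfig",
    "FluxResult",
    "CoupledFBAResult",
    "solve_fba",
    "classify_exchanges",
    "couple_cells",
    "run_stage_panel",
]

STAGES = ("primordial", "primary", "secondary", "small_antral", "large_antral", "NSN", "SN")


@dataclass(frozen=True)
class StageConfig:
    """Objectives and measured constraints for one follicle stage."""

    stage: str
    somatic_objective: Mapping[str, float]  # reaction id -> weight
    oocyte_objective: Mapping[str, float]
    pyruvate_exchange: str
    measured_constraints: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    oxygen_rule: str = "uptake_only"  # "uptake_only" | "free"
    oxygen_exchange: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.oxygen_rule not in ("uptake_only", "free"):
            raise ValueError("oxygen_rule must be 'uptake_only' or 'free'")
        if not self.somatic_objective or not self.oocyte_objective:
            raise ValueError("objectives must be non-empty")
        object.__setattr__(self, "somatic_objective", dict(self.somatic_objective))
        object.__setattr__(self, "oocyte_objective", dict(self.oocyte_objective))
        object.__setattr__(self, "measured_constraints", dict(self.measured_constraints))


@dataclass
class FluxResult:
    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded | failed

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class CoupledFBAResult:
    stage: str
    somatic: FluxResult
    oocyte: FluxResult
    cell_ratio: float
    oocyte_medium: dict[str, float]  # metabolite -> uptake availability
    exchanged: pd.DataFrame  # metabolite, cell_type, direction, flux
    uptake_multiplier: float
    converged: bool
    residual: float
    n_iterations: int


def solve_fba(
    model: MetabolicModel,
    objective: Mapping[str, float],
    direction: str = "max",
    bounds_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> FluxResult:
    """LP optimum of a weighted reaction objective at steady state."""
    if not objective:
        raise ValueError("objective must be non-empty")
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    work = model.with_bounds(bounds_overrides) if bounds_overrides else model
    ridx = work.reaction_index
    missing = set(objective) - set(ridx)
    if missing:
        raise ModelError(f"objective references unknown reactions: {sorted(missing)}")
    c = np.zeros(len(work.reactions))
    for rid, wgt in objective.items():
        c[ridx[rid]] = wgt
    res: LPResult = solve_lp(work, c, maximize=(direction == "max"))
    fluxes = (
        {r.id: float(res.fluxes[j]) for j, r in enumerate(work.reactions)}
        if res.fluxes is not None
        else {}
    )
    return FluxResult(fluxes=fluxes, objective_value=res.objective_value, status=res.status)


def classify_exchanges(
    model: MetabolicModel,
    result: FluxResult,
    cell_type: str = "cell",
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Secreted/consumed calls from exchange fluxes of an optimal solution."""
    if not result.optimal:
        raise ValueError(f"cannot classify exchanges of a {result.status} solution")
    rows = []
    for r in model.exchanges:
        (met,) = r.metabolites
        v = result.fluxes.get(r.id, 0.0)
        if v > tol:
            direction = "secreted"
        elif v < -tol:
            direction = "consumed"
        else:
            continue
        rows.append(
            {"metabolite": met, "cell_type": cell_type, "direction": direction, "flux": v}
        )
    return pd.DataFrame(rows, columns=["metabolite", "cell_type", "direction", "flux"])


def _net_exchange(model: MetabolicModel, result: FluxResult) -> dict[str, float]:
    out: dict[str, float] = {}
    for r in model.exchanges:
        (met,) = r.metabolites
        out[met] = out.get(met, 0.0) + result.fluxes.get(r.id, 0.0)
    return out


def _stage_bounds(
    model: MetabolicModel, config: StageConfig, somatic: bool
) -> dict[str, tuple[float, float]]:
    overrides: dict[str, tuple[float, float]] = {}
    for rid, (lb, ub) in config.measured_constraints.items():
        if rid in model.reaction_index:
            overrides[rid] = (lb, ub)
    if somatic and config.oxygen_exchange and config.oxygen_exchange in model.reaction_index:
        rxn = model.reaction(config.oxygen_exchange)
        lb, ub = overrides.get(config.oxygen_exchange, (rxn.lower_bound, rxn.upper_bound))
        if config.oxygen_rule == "uptake_only":
            overrides[config.oxygen_exchange] = (lb, min(ub, 0.0))
    return overrides


def couple_cells(
    somatic_model: MetabolicModel,
    oocyte_model: MetabolicModel,
    stage_config: StageConfig,
    cell_ratio: float,
    plasma: Mapping[str, float],
    pyruvate_target: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> CoupledFBAResult:
    """Couple somatic and oocyte FBA through shared exchange metabolites.

    ``plasma`` maps extracellular metabolite id to its maximal uptake flux.
    The somatic medium is ``u * plasma`` for a scalar ``u`` in [0, 1] found
    by bisection so that somatic pyruvate secretion matches
    ``pyruvate_target`` (if None, ``u = 1`` is used directly).  The oocyte
    medium availability for each metabolite is then

        plasma + cell_ratio * somatic net secretion,   floored at 0.

    Non-convergence returns a flagged result; an infeasible stage raises.
    """
    if cell_ratio < 0:
        raise ValueError("cell_ratio must be non-negative")
    pyr_ex = stage_config.pyruvate_exchange
    for name, mdl in (("somatic", somatic_model), ("oocyte", oocyte_model)):
        if pyr_ex not in mdl.reaction_index:
            raise ModelError(f"{name} model lacks pyruvate exchange {pyr_ex!r}")

    stage_somatic = _stage_bounds(somatic_model, stage_config, somatic=True)
    stage_oocyte = _stage_bounds(oocyte_model, stage_config, somatic=False)

    def somatic_solution(u: float) -> FluxResult:
        medium = {met: u * float(up) for met, up in plasma.items()}
        constrained = apply_medium(somatic_model, medium)
        res = solve_fba(
            constrained, stage_config.somatic_objective, "max", stage_somatic or None
        )
        if res.status != "optimal":
            raise RuntimeError(
                f"somatic FBA {res.status} at stage {stage_config.stage!r} "
                f"(uptake multiplier {u:.4g})"
            )
        return res

    def pyr_secretion(res: FluxResult) -> float:
        return res.fluxes.get(pyr_ex, 0.0)

    n_iter = 0
    if pyruvate_target is None:
        u = 1.0
        som = somatic_solution(u)
        residual = 0.0
        converged = True
        n_iter = 1
    else:
        hi = 1.0
        som_hi = somatic_solution(hi)
        n_iter = 1
        if pyr_secretion(som_hi) <= pyruvate_target + tol:
            # even the full plasma allowance cannot overshoot the target
            u, som = hi, som_hi
            residual = abs(pyr_secretion(som) - pyruvate_target)
            converged = residual <= tol
        else:
            lo = 0.0
            som_lo = somatic_solution(lo)
            n_iter += 1
            u, som = lo, som_lo
            residual = abs(pyr_secretion(som) - pyruvate_target)
            converged = residual <= tol
            while not converged and n_iter < max_iter:
                mid = 0.5 * (lo + hi)
                som_mid = somatic_solution(mid)
                n_iter += 1
                sec = pyr_secretion(som_mid)
                if sec > pyruvate_target:
                    hi = mid
                else:
                    lo = mid
                if abs(sec - pyruvate_target) < residual:
                    u, som, residual = mid, som_mid, abs(sec - pyruvate_target)
                converged = residual <= tol

    net = _net_exchange(somatic_model, som)
    oocyte_medium: dict[str, float] = {}
    shared = set(plasma) | {m for m in net if oocyte_model.exchange_for(m) is not None}
    for met in sorted(shared):
        if oocyte_model.exchange_for(met) is None:
            continue
        avail = float(plasma.get(met, 0.0)) + cell_ratio * net.get(met, 0.0)
        oocyte_medium[met] = max(avail, 0.0)

    oo_constrained = apply_medium(oocyte_model, oocyte_medium)
    oo = solve_fba(oo_constrained, stage_config.oocyte_objective, "max", stage_oocyte or None)
    if oo.status != "optimal":
        raise RuntimeError(f"oocyte FBA {oo.status} at stage {stage_config.stage!r}")

    exchanged = pd.concat(
        [
            classify_exchanges(somatic_model, som, "somatic", tol=tol),
            classify_exchanges(oocyte_model, oo, "oocyte", tol=tol),
        ],
        ignore_index=True,
    )
    exchanged.insert(0, "stage", stage_config.stage)
    return CoupledFBAResult(
        stage=stage_config.stage,
        somatic=som,
        oocyte=oo,
        cell_ratio=cell_ratio,
        oocyte_medium=oocyte_medium,
        exchanged=exchanged,
        uptake_multiplier=u,
        converged=converged,
        residual=residual,
        n_iterations=n_iter,
    )


def run_stage_panel(
    somatic_model: MetabolicModel,
    oocyte_model: MetabolicModel,
    stage_configs: Sequence[StageConfig],
    cell_counts: Mapping[str, float],
    plasma: Mapping[str, float],
    pyruvate_targets: Mapping[str, float] | None = None,
    tol: float = 1e-6,
) -> list[CoupledFBAResult]:
    """One coupled solve per follicle stage.

    ``cell_counts`` maps stage to somatic cells per oocyte (histology
    module output); missing stages raise.
    """
    results = []
    for cfg in stage_configs:
        if cfg.stage not in cell_counts:
            raise KeyError(f"no somatic cell count for stage {cfg.stage!r}")
        target = None if pyruvate_targets is None else pyruvate_targets.get(cfg.stage)
        results.append(
            couple_cells(
                somatic_model,
                oocyte_model,
                cfg,
                cell_ratio=float(cell_counts[cfg.stage]),
                plasma=plasma,
                pyruvate_target=target,
                tol=tol,
            )
        )
    return results
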