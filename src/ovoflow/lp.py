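"""Thin linear-programming layer over ``scipy.optimize.linprog`` (HiGHS).

All flux LPs in the package share the same structure: optimise a linear
objective over the steady-state polytope { v : S v = 0, lb <= v <= ub }.
This module centralises solver calls so the tolerance and method are set in
one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = ["LPResult", "solve_lp", "solve_raw_lp"]

_METHOD = "highs"


@dataclass
class LPResult:
    status: str  # optimal | infeasible | unbounded | failed
    objective_value: float
    fluxes: np.ndarray | None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_raw_lp(
    c: np.ndarray,
    A_eq: sparse.spmatrix | None,
    b_eq: np.ndarray | None,
    bounds: list[tuple[float, float]],
    A_ub: sparse.spmatrix | None = None,
    b_ub: np.ndarray | None = None,
    maximize: bool = False,
) -> LPResult:
    """Solve min (or max) c.x subject to A_eq x = b_eq, A_ub x <= b_ub, bounds."""
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method=_METHOD,
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return LPResult(status=status, objective_value=float("nan"), fluxes=None)
    return LPResult(status="optimal", objective_value=sign * float(res.fun), fluxes=res.x)


def solve_lp(model: MetabolicModel, c: np.ndarray, maximize: bool = False) -> LPResult:
    """Optimise ``c . v`` over the model's steady-state flux polytope."""
    lb, ub = model.bounds
    bounds = list(zip(lb, ub))
    n_mets = len(model.metabolites)
    A_eq = model.S if n_mets else None
    b_eq = np.zeros(n_mets) if n_mets else None
    return solve_raw_lp(c, A_eq, b_eq, bounds, maximize=maximize)
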