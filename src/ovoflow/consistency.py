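"""Flux-consistency analysis and context-specific subnetwork extraction.

Two questions are answered here.  First, which reactions of a model can
carry flux at all ("blocked" reactions cannot exceed a small threshold
``epsilon`` in any steady state; metabolites left without an active producer
or consumer are "dead ends").  Second, given a *core* of reactions that the
transcriptome says must be active in a cell type, what is a near-minimal
flux-consistent subnetwork containing that core?  The extraction follows
the FASTCORE scheme of two alternating LPs:

* LP7 maximises the number of still-unsatisfied core reactions pushed to a
  flux of at least ``epsilon``;
* LP10 minimises a weighted L1 penalty on non-core flux while holding the
  newly satisfied core reactions at ``epsilon``.

Reversible reactions are handled by the direction-flipping scheme of the
original algorithm rather than by splitting the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .lp import solve_raw_lp
from .model import MetabolicModel, evaluate_gpr

__all__ = [
    "CoreSet",
    "ConsistencyReport",
    "ExpressionRule",
    "flux_variability",
    "find_blocked",
    "fastcore",
    "expression_core",
    "FastcoreError",
    "InfeasibleModelError",
]

DEFAULT_EPSILON = 1e-4


class InfeasibleModelError(RuntimeError):
    pass


class FastcoreError(RuntimeError):
    def __init__(self, message: str, reaction_ids: Sequence[str] = ()):
        super().__init__(message)
        self.reaction_ids = list(reaction_ids)


@dataclass(frozen=True)
class CoreSet:
    """Reactions required to be active in a context-specific extraction."""

    reaction_ids: frozenset[str]
    derivation: str = "manual"  # "expression" | "manual"
    expression_rule: "ExpressionRule | None" = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "reaction_ids", frozenset(self.reaction_ids))


@dataclass
class ConsistencyReport:
    blocked_reactions: frozenset[str]
    dead_end_metabolites: frozenset[str]
    epsilon: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": r, "kind": "blocked_reaction"} for r in sorted(self.blocked_reactions)]
        rows += [{"id": m, "kind": "dead_end_metabolite"} for m in sorted(self.dead_end_metabolites)]
        return pd.DataFrame(rows, columns=["id", "kind"])


# ---------------------------------------------------------------------------
# Flux variability analysis
# ---------------------------------------------------------------------------


def flux_variability(
    model: MetabolicModel,
    reaction_ids: Iterable[str] | None = None,
    objective: dict[str, float] | None = None,
    fraction_of_optimum: float | None = None,
) -> pd.DataFrame:
    """Per-reaction (min, max) flux over { v : S v = 0, lb <= v <= ub }.

    If ``objective`` and ``fraction_of_optimum`` are given, the polytope is
    additionally cut by ``c.v >= fraction * optimum``.
    """
    rids = list(reaction_ids) if reaction_ids is not None else [r.id for r in model.reactions]
    ridx = model.reaction_index
    unknown = [r for r in rids if r not in ridx]
    if unknown:
        raise KeyError(f"unknown reactions: {unknown}")

    n = len(model.reactions)
    lb, ub = model.bounds
    bounds = list(zip(lb, ub))
    A_eq = model.S
    b_eq = np.zeros(len(model.metabolites))
    A_ub = None
    b_ub = None

    if objective is not None and fraction_of_optimum is not None:
        c_obj = np.zeros(n)
        for rid, w in objective.items():
            c_obj[ridx[rid]] = w
        res = solve_raw_lp(c_obj, A_eq, b_eq, bounds, maximize=True)
        if res.status != "optimal":
            raise InfeasibleModelError(
                f"objective LP is {res.status}: steady-state constraints S.v=0 "
                "with the configured bounds admit no optimum"
            )
        A_ub = sparse.csr_matrix(-c_obj)
        b_ub = np.array([-fraction_of_optimum * res.objective_value])

    rows = []
    for rid in rids:
        j = ridx[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo = solve_raw_lp(c, A_eq, b_eq, bounds, A_ub=A_ub, b_ub=b_ub, maximize=False)
        hi = solve_raw_lp(c, A_eq, b_eq, bounds, A_ub=A_ub, b_ub=b_ub, maximize=True)
        if lo.status != "optimal" or hi.status != "optimal":
            raise InfeasibleModelError(
                f"FVA for reaction {rid!r} failed: steady-state constraint set "
                f"(S.v = 0 with bounds) is {lo.status if lo.status != 'optimal' else hi.status}"
            )
        rows.append({"reaction_id": rid, "minimum": lo.objective_value, "maximum": hi.objective_value})
    return pd.DataFrame(rows).set_index("reaction_id")


# ---------------------------------------------------------------------------
# Blocked reactions / dead ends
# ---------------------------------------------------------------------------


def _lp7_flux(
    S: sparse.csc_matrix,
    lb: np.ndarray,
    ub: np.ndarray,
    J: np.ndarray,
    epsilon: float,
) -> np.ndarray | None:
    """LP7: maximise the number of reactions in J with flux >= epsilon.

    Variables [v, z]; maximise sum z subject to z_j <= v_j, 0 <= z_j <= eps.
    Returns the flux vector v, or None on solver failure.
    """
    m, n = S.shape
    nj = len(J)
    if nj == 0:
        return np.zeros(n)
    c = np.concatenate([np.zeros(n), -np.ones(nj)])  # minimise -> maximise sum z
    A_eq = sparse.hstack([S, sparse.csc_matrix((m, nj))], format="csr") if m else None
    b_eq = np.zeros(m) if m else None
    # z_j - v_j <= 0
    rows = np.arange(nj)
    Ij = sparse.csr_matrix((np.ones(nj), (rows, J)), shape=(nj, n))
    A_ub = sparse.hstack([-Ij, sparse.eye(nj, format="csr")], format="csr")
    b_ub = np.zeros(nj)
    bounds = list(zip(lb, ub)) + [(0.0, epsilon)] * nj
    from scipy.optimize import linprog

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        return None
    return res.x[:n]


def find_blocked(model: MetabolicModel, epsilon: float = DEFAULT_EPSILON) -> ConsistencyReport:
    """Identify blocked reactions and the dead-end metabolites they imply.

    A reaction is blocked iff its FVA range stays within ``(-epsilon,
    epsilon)`` with the model's configured bounds.  An LP7 sweep (forward,
    then with reversible directions flipped) marks most flux-carrying
    reactions in two solver calls; only the remainder is checked with
    per-reaction LPs.
    """
    n = len(model.reactions)
    if n == 0:
        return ConsistencyReport(frozenset(), frozenset(), epsilon)
    S = model.S
    lb, ub = model.bounds
    all_idx = np.arange(n)

    unblocked = np.zeros(n, dtype=bool)
    v = _lp7_flux(S, lb, ub, all_idx, epsilon)
    if v is not None:
        unblocked |= np.abs(v) >= 0.99 * epsilon
    rev = lb < 0
    if rev.any():
        # flip reversible directions to catch reactions that only carry
        # negative flux
        lb2, ub2 = lb.copy(), ub.copy()
        lb2[rev], ub2[rev] = -ub[rev], -lb[rev]
        v = _lp7_flux(S, lb2, ub2, all_idx, epsilon)
        if v is not None:
            w = v.copy()
            w[rev] = -w[rev]
            unblocked |= np.abs(w) >= 0.99 * epsilon

    bounds = list(zip(lb, ub))
    b_eq = np.zeros(S.shape[0])
    blocked_ids: set[str] = set()
    for j in np.flatnonzero(~unblocked):
        c = np.zeros(n)
        c[j] = 1.0
        hi = solve_raw_lp(c, S, b_eq, bounds, maximize=True)
        if hi.status == "optimal" and hi.objective_value >= epsilon:
            continue
        lo = solve_raw_lp(c, S, b_eq, bounds, maximize=False)
        if lo.status == "optimal" and abs(lo.objective_value) >= epsilon:
            continue
        if hi.status != "optimal" or lo.status != "optimal":
            raise InfeasibleModelError(
                f"flux bounds for reaction {model.reactions[j].id!r} could not "
                "be computed: steady-state LP not optimal"
            )
        blocked_ids.add(model.reactions[j].id)

    # dead ends: metabolite with no active producer or no active consumer
    dead: set[str] = set()
    active = [r for r in model.reactions if r.id not in blocked_ids]
    producers: dict[str, int] = {}
    consumers: dict[str, int] = {}
    for r in active:
        for met, coeff in r.metabolites.items():
            makes = coeff > 0 or r.reversible
            takes = coeff < 0 or r.reversible
            if makes:
                producers[met] = producers.get(met, 0) + 1
            if takes:
                consumers[met] = consumers.get(met, 0) + 1
    for m in model.metabolites:
        if producers.get(m.id, 0) == 0 or consumers.get(m.id, 0) == 0:
            dead.add(m.id)
    return ConsistencyReport(frozenset(blocked_ids), frozenset(dead), epsilon)


# ---------------------------------------------------------------------------
# FASTCORE extraction
# ---------------------------------------------------------------------------

_LP10_SCALE = 1e5


def _lp10_flux(
    S: sparse.csc_matrix,
    lb: np.ndarray,
    ub: np.ndarray,
    K: np.ndarray,
    P: np.ndarray,
    epsilon: float,
) -> np.ndarray | None:
    """LP10: minimise the L1 norm of fluxes through P while forcing v_K >= eps.

    Bounds are rescaled by a large factor for numerical headroom, as in the
    original algorithm.
    """
    m, n = S.shape
    np_ = len(P)
    if len(K) == 0:
        return None
    lb_s = lb * _LP10_SCALE
    ub_s = ub * _LP10_SCALE
    lb_s[K] = np.maximum(lb_s[K], epsilon * _LP10_SCALE)
    if np_ == 0:
        c = np.zeros(n)
        res = solve_raw_lp(c, S if m else None, np.zeros(m) if m else None, list(zip(lb_s, ub_s)))
        return None if res.fluxes is None else res.fluxes / _LP10_SCALE
    zcap = np.maximum(np.abs(ub[P]), np.abs(lb[P])) * _LP10_SCALE
    c = np.concatenate([np.zeros(n), np.ones(np_)])
    A_eq = sparse.hstack([S, sparse.csc_matrix((m, np_))], format="csr") if m else None
    b_eq = np.zeros(m) if m else None
    rows = np.arange(np_)
    Ip = sparse.csr_matrix((np.ones(np_), (rows, P)), shape=(np_, n))
    Eye = sparse.eye(np_, format="csr")
    A_ub = sparse.vstack([sparse.hstack([Ip, -Eye]), sparse.hstack([-Ip, -Eye])], format="csr")
    b_ub = np.zeros(2 * np_)
    bounds = list(zip(lb_s, ub_s)) + [(0.0, z) for z in zcap]
    from scipy.optimize import linprog

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        return None
    return res.x[:n] / _LP10_SCALE


def _find_sparse_mode(
    S: sparse.csc_matrix,
    lb: np.ndarray,
    ub: np.ndarray,
    J: np.ndarray,
    P: np.ndarray,
    singleton: bool,
    epsilon: float,
) -> np.ndarray:
    if len(J) == 0:
        return np.array([], dtype=int)
    target = J[:1] if singleton else J
    v = _lp7_flux(S, lb, ub, target, epsilon)
    if v is None:
        return np.array([], dtype=int)
    K = np.array([j for j in target if v[j] >= 0.99 * epsilon], dtype=int)
    if len(K) == 0:
        return np.array([], dtype=int)
    v = _lp10_flux(S, lb, ub, K, P, epsilon)
    if v is None:
        return np.array([], dtype=int)
    # LP10 solves in bounds scaled by _LP10_SCALE; _lp10_flux returns the
    # unscaled vector, so the support threshold rescales accordingly.
    return np.flatnonzero(np.abs(v) >= 0.99 * epsilon / _LP10_SCALE)


def _cascade_reduce(
    model: MetabolicModel, keep: set[str], core: frozenset[str], epsilon: float
) -> set[str] | None:
    """Drop blocked reactions from ``keep`` until consistent; None if the
    cascade would swallow a core reaction."""
    keep = set(keep)
    while True:
        blocked = find_blocked(model.subset(sorted(keep)), epsilon).blocked_reactions
        if not blocked:
            return keep
        if blocked & core:
            return None
        keep -= blocked


def _polish_extraction(
    model: MetabolicModel, A: set[str], core: frozenset[str], epsilon: float
) -> set[str]:
    """Local search shrinking the extracted set.

    Moves: remove one non-core reaction plus everything its removal blocks
    (cascade), and add one outside reaction followed by the same cascade
    pruning — the addition can unlock a shorter route whose adoption
    retires a longer one.  Each accepted move strictly reduces the set, so
    termination is guaranteed; consistency and core containment are
    invariant.  Cost grows with model size; disable via ``polish=False``
    for large inputs.
    """

    def prune(current: set[str]) -> set[str]:
        improved = True
        while improved:
            improved = False
            for r in sorted(current - core):
                reduced = _cascade_reduce(model, current - {r}, core, epsilon)
                if reduced is not None and len(reduced) < len(current):
                    current = reduced
                    improved = True
                    break
        return current

    A = prune(A)
    outside = {r.id for r in model.reactions}
    improved = True
    while improved:
        improved = False
        for s in sorted(outside - A):
            candidate = prune(A | {s})
            if len(candidate) < len(A):
                A = candidate
                improved = True
                break
    return A


def fastcore(
    model: MetabolicModel,
    core: CoreSet,
    epsilon: float = DEFAULT_EPSILON,
    polish: bool = False,
) -> MetabolicModel:
    """Extract a near-minimal flux-consistent sub-model containing ``core``.

    The input model must itself be flux-consistent (no blocked reactions);
    a blocked core reaction raises :class:`FastcoreError` listing the ids.
    An empty core returns an empty sub-model.  Ties between equally small
    non-core completions are broken deterministically by the LP solver and
    reaction order.

    ``polish`` runs a cardinality-reducing local search on the extracted
    set (see :func:`_polish_extraction`); it never violates the consistency
    or core-superset guarantees and brings the non-core count very close to
    the true minimum on small models, but costs O(|reactions| x consistency
    checks) — leave it off for genome-scale inputs.
    """
    ridx = model.reaction_index
    unknown = core.reaction_ids - set(ridx)
    if unknown:
        raise FastcoreError(
            f"core contains reactions absent from the model: {sorted(unknown)}",
            sorted(unknown),
        )
    if not core.reaction_ids:
        return MetabolicModel(metabolites=[], reactions=[], id=model.id + "_core")

    n = len(model.reactions)
    S0 = model.S.tocsc()
    lb, ub = model.bounds
    lb, ub = lb.copy(), ub.copy()
    sign = np.ones(n)

    def flip(idx: np.ndarray) -> None:
        # flip reaction direction: negate the S column and mirror bounds
        sign[idx] *= -1.0
        lb[idx], ub[idx] = -ub[idx], -lb[idx]

    S = S0  # re-derived after each flip
    def current_S():
        return S0.multiply(sign).tocsc()

    # canonical orientation: reverse-only reactions (ub <= 0, lb < 0) are
    # flipped so every irreversible reaction runs forward, as the algorithm
    # assumes; support sets are orientation-free.
    reverse_only = np.flatnonzero((ub <= 0) & (lb < 0))
    if len(reverse_only):
        flip(reverse_only)
    S = current_S()
    irreversible = np.flatnonzero(~(np.array([r.reversible for r in model.reactions])))
    irr_set = set(irreversible.tolist())
    C = np.array(sorted(ridx[r] for r in core.reaction_ids), dtype=int)
    c_set = set(C.tolist())
    N = set(range(n))

    def ids(idxs: Iterable[int]) -> list[str]:
        return sorted(model.reactions[i].id for i in idxs)

    flipped = False
    singleton = False
    J = np.array(sorted(c_set & irr_set), dtype=int)
    P = np.array(sorted(N - c_set), dtype=int)
    supp = _find_sparse_mode(S, lb, ub, J, P, singleton, epsilon)
    missing = set(J.tolist()) - set(supp.tolist())
    if missing:
        raise FastcoreError(
            f"irreversible core reactions cannot carry flux (blocked in the "
            f"input model): {ids(missing)}",
            ids(missing),
        )
    A = set(supp.tolist())
    J_set = c_set - A
    while J_set:
        P = np.array(sorted(set(P.tolist()) - A), dtype=int)
        J = np.array(sorted(J_set), dtype=int)
        supp = _find_sparse_mode(S, lb, ub, J, P, singleton, epsilon)
        A |= set(supp.tolist())
        if J_set & A:
            J_set -= A
            flipped = False
        else:
            if singleton:
                Ji = {int(J[0])} - irr_set
            else:
                Ji = J_set - irr_set
            if flipped or not Ji:
                if singleton:
                    raise FastcoreError(
                        f"core reactions remain infeasible (blocked in the "
                        f"input model): {ids(J_set)}",
                        ids(J_set),
                    )
                flipped = False
                singleton = True
            else:
                flip(np.array(sorted(Ji), dtype=int))
                S = current_S()
                flipped = True

    keep = {model.reactions[i].id for i in sorted(A)}
    if polish:
        keep = _polish_extraction(model, keep, frozenset(core.reaction_ids), epsilon)
    return model.subset(sorted(keep), id_suffix="_core")


# ---------------------------------------------------------------------------
# Expression-defined cores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionRule:
    """How a gene is called "expressed" from an intensity table.

    If the table carries a boolean ``detected`` column and ``use_detected``
    is set, detection decides.  Otherwise a gene is expressed when its
    intensity exceeds the table-wide ``quantile`` (default: median).
    """

    use_detected: bool = True
    quantile: float = 0.5


def expressed_genes(expression: pd.DataFrame, rule: ExpressionRule | None = None) -> frozenset[str]:
    rule = rule or ExpressionRule()
    if "gene" not in expression.columns:
        raise KeyError("expression table needs a 'gene' column")
    if rule.use_detected and "detected" in expression.columns:
        mask = expression["detected"].astype(bool)
        return frozenset(expression.loc[mask, "gene"])
    if "intensity" not in expression.columns:
        raise KeyError("expression table needs an 'intensity' column")
    thr = expression["intensity"].quantile(rule.quantile)
    return frozenset(expression.loc[expression["intensity"] > thr, "gene"])


def expression_core(
    model: MetabolicModel,
    expression: pd.DataFrame,
    rule: ExpressionRule | None = None,
) -> CoreSet:
    """Reactions whose GPR evaluates true under the expressed-gene call.

    DNF semantics: a reaction is in the core iff at least one of its gene
    conjunctions is fully expressed.  Reactions without a GPR are never
    placed in the core by expression.
    """
    rule = rule or ExpressionRule()
    expr = expressed_genes(expression, rule)
    model_genes = model.genes
    if not (set(expression["gene"]) & set(model_genes)):
        raise ValueError(
            "no overlap between expression gene ids and model gene ids; "
            "check identifier namespaces"
        )
    core = {
        r.id
        for r in model.reactions
        if r.gene_sets and evaluate_gpr(r.gene_sets, expr & model_genes)
    }
    return CoreSet(frozenset(core), derivation="expression", expression_rule=rule)
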