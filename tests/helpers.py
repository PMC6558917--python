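"""Independent oracles used by the test suite.

Everything here is deliberately written against the raw LP solver / dense
linear algebra / graph combinatorics, NOT against the package's own
implementations, so tests compare two independent routes to the same
quantity.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from ovoflow.model import MetabolicModel


# ---------------------------------------------------------------------------
# Per-reaction two-LP FVA oracle
# ---------------------------------------------------------------------------


def fva_oracle(model: MetabolicModel) -> dict[str, tuple[float, float]]:
    """min/max flux per reaction by two direct linprog calls each."""
    S = model.S.toarray()
    lb, ub = model.bounds
    n = len(model.reactions)
    bounds = list(zip(lb, ub))
    out = {}
    for j, r in enumerate(model.reactions):
        c = np.zeros(n)
        c[j] = 1.0
        lo = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
        hi = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
        assert lo.status == 0 and hi.status == 0
        out[r.id] = (float(lo.fun), float(-hi.fun))
    return out


def blocked_oracle(model: MetabolicModel, epsilon: float = 1e-4) -> frozenset[str]:
    fva = fva_oracle(model)
    return frozenset(
        rid for rid, (lo, hi) in fva.items() if abs(lo) < epsilon and hi < epsilon
    )


# ---------------------------------------------------------------------------
# Combinatorial consistency oracle for unit one-in/one-out networks
# ---------------------------------------------------------------------------


def _is_unit_network(model: MetabolicModel) -> bool:
    for r in model.reactions:
        coeffs = sorted(r.metabolites.values())
        if r.is_exchange:
            continue
        if coeffs not in ([-1.0, 1.0],):
            return False
    return True


def subset_consistent(model: MetabolicModel, reaction_ids: set[str]) -> bool:
    """Exact consistency of a reaction subset for unit 1->1 networks.

    With unit stoichiometry and one substrate/one product per internal
    reaction, S v = 0 with v >= 0 (after orienting reversibles) is a
    circulation problem on the metabolite digraph with an environment
    node: an arc can carry positive flux iff both endpoints lie in the
    same strongly connected component.
    """
    assert _is_unit_network(model), "combinatorial oracle needs a unit network"
    g = nx.DiGraph()
    g.add_node("__env__")
    arcs: list[tuple[str, str, str]] = []  # (rid, u, v)
    for r in model.reactions:
        if r.id not in reaction_ids:
            continue
        if r.is_exchange:
            (met,) = r.metabolites
            if r.lower_bound < 0:
                arcs.append((r.id, "__env__", met))
            if r.upper_bound > 0:
                arcs.append((r.id, met, "__env__"))
        else:
            sub = next(m for m, c in r.metabolites.items() if c < 0)
            prod = next(m for m, c in r.metabolites.items() if c > 0)
            if r.upper_bound > 0:
                arcs.append((r.id, sub, prod))
            if r.lower_bound < 0:
                arcs.append((r.id, prod, sub))
    for _, u, v in arcs:
        g.add_edge(u, v)
    scc_of: dict[str, int] = {}
    for i, comp in enumerate(nx.strongly_connected_components(g)):
        for node in comp:
            scc_of[node] = i
    # every reaction must have at least one of its directions inside an SCC
    per_rxn_ok: dict[str, bool] = {rid: False for rid in reaction_ids}
    for rid, u, v in arcs:
        if scc_of[u] == scc_of[v]:
            per_rxn_ok[rid] = True
    return all(per_rxn_ok.values())


def min_extra_reactions(model: MetabolicModel, core: set[str]) -> int:
    """Brute-force minimum number of non-core reactions whose addition makes
    the core part of a consistent subnetwork (subset enumeration)."""
    non_core = [r.id for r in model.reactions if r.id not in core]
    for k in range(len(non_core) + 1):
        for combo in itertools.combinations(non_core, k):
            if subset_consistent(model, core | set(combo)):
                return k
    raise AssertionError("no consistent superset exists (model inconsistent)")


# ---------------------------------------------------------------------------
# Dense map-equation evaluation
# ---------------------------------------------------------------------------


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 0 else 0.0


def codelength_oracle(graph: nx.Graph, flows: dict, damping: float, partition: dict) -> float:
    """Two-level map-equation codelength from the dense transition matrix."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for a, b, d in graph.edges(data=True):
        w = d.get("weight", 1)
        W[idx[a], idx[b]] += w
        W[idx[b], idx[a]] += w
    k = W.sum(axis=1)
    P = np.zeros((n, n))
    for i in range(n):
        if k[i] > 0:
            P[i] = damping * W[i] / k[i] + (1 - damping) / n
        else:
            P[i] = 1.0 / n
    p = np.array([flows[v] for v in nodes])
    F = p[:, None] * P  # edge flows
    modules = sorted(set(partition.values()))
    L = 0.0
    q = {}
    for m in modules:
        members = [idx[v] for v in nodes if partition[v] == m]
        outside = [i for i in range(n) if i not in members]
        q[m] = F[np.ix_(members, outside)].sum()
    q_tot = sum(q.values())
    L += _plogp(q_tot)
    L -= 2 * sum(_plogp(qi) for qi in q.values())
    L -= sum(_plogp(pi) for pi in p)
    for m in modules:
        members = [idx[v] for v in nodes if partition[v] == m]
        L += _plogp(q[m] + p[members].sum())
    return L


def all_partitions(items: list):
    """Every set partition of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def optimal_codelength(graph: nx.Graph, flows: dict, damping: float) -> float:
    nodes = sorted(graph.nodes)
    best = math.inf
    for part in all_partitions(nodes):
        assign = {v: i for i, block in enumerate(part) for v in block}
        best = min(best, codelength_oracle(graph, flows, damping, assign))
    return best
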