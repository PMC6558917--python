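"""Enzyme-metabolite graphs, random-walk flows, and map-equation communities.

The bipartite graph links each enzyme (gene id) to the metabolites of the
reactions it catalyses; its one-mode projection links two enzymes with an
edge weighted by the number of metabolites they share.  Node "flows" are
the stationary visit rates of a teleporting random walk on the weighted
projection (with damping 1 on a connected graph this reduces to the
degree-proportional distribution).  Communities are found by minimising the
two-level map equation

    L(M) = q * H(Q) + sum_i p_i * H(P_i)

over partitions M, where q is the total inter-module ("exit") flow, H(Q)
the entropy of the exit-flow distribution, and H(P_i) the entropy of module
i's codebook of node visits plus its exit event.  The search is a
Louvain-style local-move/merge heuristic restarted ``n_iterations`` times
with shuffled node orders; the minimum-codelength partition is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .model import MetabolicModel

__all__ = [
    "EnzymeNetwork",
    "NodeFlows",
    "CommunityPartition",
    "DEFAULT_CURRENCY_METABOLITES",
    "build_enzyme_network",
    "node_flows",
    "map_equation_codelength",
    "detect_communities",
]

# Ubiquitous cofactors/currency species whose sharing is not evidence of a
# functional pathway link; matched on the metabolite id minus its
# compartment suffix ("atp_c" -> "atp").
DEFAULT_CURRENCY_METABOLITES = frozenset(
    {
        "h2o", "h", "atp", "adp", "amp", "pi", "ppi",
        "nad", "nadh", "nadp", "nadph", "co2", "o2",
    }
)


def strip_compartment(met_id: str) -> str:
    if "_" in met_id:
        base, _, comp = met_id.rpartition("_")
        if len(comp) <= 2 and base:
            return base
    return met_id


@dataclass
class EnzymeNetwork:
    """Bipartite enzyme-metabolite graph plus its enzyme projection."""

    enzymes: list[str]
    metabolite_nodes: list[str]
    bipartite: dict[str, frozenset[str]]  # enzyme -> metabolites it catalyses
    projection: nx.Graph  # weight = number of shared metabolites

    @property
    def w(self) -> dict[str, int]:
        """Bipartite degree of each enzyme (metabolites catalysed)."""
        return {e: len(mets) for e, mets in self.bipartite.items()}

    def enzymes_of_metabolite(self, met_id: str) -> frozenset[str]:
        return frozenset(e for e, mets in self.bipartite.items() if met_id in mets)


@dataclass
class NodeFlows:
    f: dict[str, float]
    damping: float
    tolerance: float

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.f[n] for n in order], dtype=float)


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    codelength: float  # bits

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def member_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for c in self.assignment.values():
            counts[c] = counts.get(c, 0) + 1
        return counts

    def members(self, community: int) -> list[str]:
        return sorted(n for n, c in self.assignment.items() if c == community)


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def build_enzyme_network(
    model: MetabolicModel,
    gene_subset: Iterable[str] | None = None,
    currency_exclusions: Iterable[str] | None = None,
    exclude_currency_defaults: bool = False,
    include_exchanges: bool = False,
    degree_percentile_cap: float | None = None,
) -> EnzymeNetwork:
    """Build the enzyme-metabolite bipartite graph and its projection.

    An enzyme (gene) is linked to every metabolite of every reaction whose
    GPR mentions it.  Exchange pseudo-reactions are skipped by default.
    ``currency_exclusions`` removes the named metabolite ids;
    ``exclude_currency_defaults`` additionally drops the built-in cofactor
    list in every compartment.  ``degree_percentile_cap`` (e.g. 99) removes
    the highest-degree metabolites above that percentile of bipartite
    metabolite degree.
    """
    subset = set(gene_subset) if gene_subset is not None else None
    if subset is not None:
        extra = subset - set(model.genes)
        if extra:
            raise KeyError(f"gene_subset contains ids absent from the model: {sorted(extra)}")
    excl = {str(m) for m in (currency_exclusions or ())}

    bip: dict[str, set[str]] = {}
    for r in model.reactions:
        if r.is_exchange and not include_exchanges:
            continue
        genes = r.genes
        if subset is not None:
            genes = genes & subset
        if not genes:
            continue
        for g in genes:
            bip.setdefault(g, set())
        for met in r.metabolites:
            if met in excl:
                continue
            if exclude_currency_defaults and strip_compartment(met) in DEFAULT_CURRENCY_METABOLITES:
                continue
            for g in genes:
                bip[g].add(met)

    if not bip:
        raise ValueError("no enzymes left after filtering; check gene_subset/exclusions")

    if degree_percentile_cap is not None:
        met_deg: dict[str, int] = {}
        for mets in bip.values():
            for m in mets:
                met_deg[m] = met_deg.get(m, 0) + 1
        cap = float(np.percentile(list(met_deg.values()), degree_percentile_cap))
        hubs = {m for m, d in met_deg.items() if d > cap}
        bip = {g: mets - hubs for g, mets in bip.items()}
        if not any(bip.values()):
            raise ValueError("degree cap removed every bipartite edge")

    enzymes = sorted(bip)
    met_nodes = sorted({m for mets in bip.values() for m in mets})

    # projection: weight = |shared metabolites|
    proj = nx.Graph()
    proj.add_nodes_from(enzymes)
    met_to_enz: dict[str, list[str]] = {}
    for g in enzymes:
        for m in bip[g]:
            met_to_enz.setdefault(m, []).append(g)
    weights: dict[tuple[str, str], int] = {}
    for m, gs in met_to_enz.items():
        gs = sorted(gs)
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                key = (gs[i], gs[j])
                weights[key] = weights.get(key, 0) + 1
    for (a, b), wgt in weights.items():
        proj.add_edge(a, b, weight=wgt)

    return EnzymeNetwork(
        enzymes=enzymes,
        metabolite_nodes=met_nodes,
        bipartite={g: frozenset(ms) for g, ms in bip.items()},
        projection=proj,
    )


def write_edge_list(network: EnzymeNetwork, path) -> None:
    """Weighted projection edge list as TSV (source, target, weight)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for a, b, d in sorted(network.projection.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d.get('weight', 1)}\n")


def write_pajek(network: EnzymeNetwork, path) -> None:
    """Pajek .net export of the projection, for interoperability checks
    against external map-equation tools."""
    nodes = list(network.projection.nodes)
    idx = {n: i + 1 for i, n in enumerate(nodes)}
    with open(path, "w") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for n in nodes:
            fh.write(f'{idx[n]} "{n}"\n')
        fh.write("*Edges\n")
        for a, b, d in network.projection.edges(data=True):
            fh.write(f"{idx[a]} {idx[b]} {d.get('weight', 1)}\n")


# ---------------------------------------------------------------------------
# Flows
# ---------------------------------------------------------------------------


def node_flows(
    network: EnzymeNetwork | nx.Graph,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> NodeFlows:
    """Stationary visit rates of a teleporting random walk on the projection.

    Power iteration on P = damping * W_row-normalised + (1 - damping) *
    uniform; rows without edges teleport uniformly.  With damping 1 on a
    connected undirected graph the result is proportional to weighted
    degree.
    """
    graph = network.projection if isinstance(network, EnzymeNetwork) else network
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if graph.number_of_edges() == 0:
        raise ValueError("projection graph has no edges; flows are undefined")
    idx = {node: i for i, node in enumerate(nodes)}
    W = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight", format="csr")
    deg = np.asarray(W.sum(axis=1)).ravel()
    dangling = deg == 0.0
    inv_deg = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, deg))

    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        walk = (p * inv_deg) @ W  # row-normalised step
        tele = (1.0 - damping) * p[~dangling].sum() + p[dangling].sum()
        step = damping * walk + tele / n
        new = 0.5 * (p + step)  # lazy walk: same stationary law, aperiodic
        residual = np.abs(new - p).sum()
        p = new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"flow power iteration did not converge: residual {residual:.3e} "
            f"after {max_iter} iterations (tol {tol:.1e})"
        )
    p = p / p.sum()
    return NodeFlows(f={node: float(p[idx[node]]) for node in nodes}, damping=damping, tolerance=tol)


# ---------------------------------------------------------------------------
# Map equation
# ---------------------------------------------------------------------------


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 0.0 else 0.0


class _MapState:
    """Module statistics for incremental map-equation evaluation.

    For module i with members M_i:
      S_i = sum of node flows;           n_i = member count;
      D_i = flow of non-dangling members (they step along edges with
            probability ``damping``);
      T_i = teleporting flow mass ((1-d) p for walking nodes, p for
            dangling ones);
      E_i = internal edge-flow, sum over members g of
            p_g * d * w(g, M_i) / k_g.
    Exit flow: Q_i = d * D_i - E_i + T_i * (n - n_i) / n.
    """

    def __init__(self, graph: nx.Graph, flows: Mapping[str, float], damping: float,
                 assignment: Mapping[str, int]):
        self.graph = graph
        self.d = damping
        self.nodes = sorted(graph.nodes)
        self.n = len(self.nodes)
        self.p = {v: float(flows[v]) for v in self.nodes}
        self.k = {v: float(sum(d.get("weight", 1) for _, _, d in graph.edges(v, data=True)))
                  for v in self.nodes}
        self.tau = {v: (self.p[v] if self.k[v] == 0 else (1.0 - damping) * self.p[v])
                    for v in self.nodes}
        self.const_term = -sum(_plogp(self.p[v]) for v in self.nodes)
        self.assign: dict[str, int] = dict(assignment)
        self.S: dict[int, float] = {}
        self.D: dict[int, float] = {}
        self.T: dict[int, float] = {}
        self.cnt: dict[int, int] = {}
        self.E: dict[int, float] = {}
        mods = set(self.assign.values())
        for m in mods:
            self.S[m] = self.D[m] = self.T[m] = self.E[m] = 0.0
            self.cnt[m] = 0
        for v in self.nodes:
            m = self.assign[v]
            self.S[m] += self.p[v]
            self.T[m] += self.tau[v]
            self.cnt[m] += 1
            if self.k[v] > 0:
                self.D[m] += self.p[v]
        for m in mods:
            self.E[m] = 0.0
        for a, b, data in graph.edges(data=True):
            if self.assign[a] == self.assign[b]:
                w = data.get("weight", 1)
                m = self.assign[a]
                contrib = 0.0
                if self.k[a] > 0:
                    contrib += self.p[a] * self.d * w / self.k[a]
                if self.k[b] > 0:
                    contrib += self.p[b] * self.d * w / self.k[b]
                self.E[m] += contrib
        # cached codelength terms, maintained incrementally by move_node
        self._q: dict[int, float] = {}
        self._q_tot = 0.0
        self._mod_sum = 0.0  # sum over modules of (-2 plogp(q_m) + plogp(q_m + S_m))
        for m in list(self.S):
            q = self.exit_flow(m)
            self._q[m] = q
            self._q_tot += q
            self._mod_sum += -2.0 * _plogp(q) + _plogp(q + self.S[m])

    def exit_flow(self, m: int) -> float:
        q = self.d * self.D[m] - self.E[m] + self.T[m] * (self.n - self.cnt[m]) / self.n
        return max(q, 0.0)

    def _retire_module_term(self, m: int) -> None:
        q = self._q.pop(m)
        self._q_tot -= q
        self._mod_sum -= -2.0 * _plogp(q) + _plogp(q + self.S[m])

    def _restore_module_term(self, m: int) -> None:
        q = self.exit_flow(m)
        self._q[m] = q
        self._q_tot += q
        self._mod_sum += -2.0 * _plogp(q) + _plogp(q + self.S[m])

    def codelength(self) -> float:
        return _plogp(self._q_tot) + self.const_term + self._mod_sum

    # -- node moves --------------------------------------------------------

    def _edge_flow_between(self, v: str, module: int) -> tuple[float, float]:
        """(out, in) directed edge-flow between node v and module members."""
        out = 0.0
        inn = 0.0
        for _, nb, data in self.graph.edges(v, data=True):
            if self.assign.get(nb) == module and nb != v:
                w = data.get("weight", 1)
                if self.k[v] > 0:
                    out += self.p[v] * self.d * w / self.k[v]
                if self.k[nb] > 0:
                    inn += self.p[nb] * self.d * w / self.k[nb]
        return out, inn

    def move_node(self, v: str, target: int) -> None:
        src = self.assign[v]
        if src == target:
            return
        e_out_src, e_in_src = self._edge_flow_between(v, src)
        self._retire_module_term(src)
        self.S[src] -= self.p[v]
        self.T[src] -= self.tau[v]
        self.cnt[src] -= 1
        if self.k[v] > 0:
            self.D[src] -= self.p[v]
        self.E[src] -= e_out_src + e_in_src
        if self.cnt[src] == 0:
            del self.S[src], self.T[src], self.cnt[src], self.D[src], self.E[src]
        else:
            self._restore_module_term(src)
        fresh = target not in self.S
        if fresh:
            self.S[target] = self.T[target] = self.D[target] = self.E[target] = 0.0
            self.cnt[target] = 0
        else:
            self._retire_module_term(target)
        self.assign[v] = target
        e_out_t, e_in_t = self._edge_flow_between(v, target)
        # after reassignment; _edge_flow_between skips v itself
        self.S[target] += self.p[v]
        self.T[target] += self.tau[v]
        self.cnt[target] += 1
        if self.k[v] > 0:
            self.D[target] += self.p[v]
        self.E[target] += e_out_t + e_in_t
        self._restore_module_term(target)


def map_equation_codelength(
    network: EnzymeNetwork | nx.Graph,
    flows: NodeFlows,
    partition: Mapping[str, int] | CommunityPartition,
) -> float:
    """Two-level map-equation codelength (bits) of a partition.

    Exit probabilities are computed from inter-community flow of the same
    teleporting walk that produced ``flows``.
    """
    graph = network.projection if isinstance(network, EnzymeNetwork) else network
    assign = partition.assignment if isinstance(partition, CommunityPartition) else dict(partition)
    missing = set(graph.nodes) - set(assign)
    if missing:
        raise KeyError(f"partition is missing nodes: {sorted(missing)}")
    state = _MapState(graph, flows.f, flows.damping, assign)
    return state.codelength()


# ---------------------------------------------------------------------------
# Community detection
# ---------------------------------------------------------------------------


def _local_moves(state: _MapState, order: list[str], rng: np.random.Generator) -> bool:
    """One pass of single-node moves; returns True if anything improved."""
    improved = False
    current_L = state.codelength()
    for v in order:
        src = state.assign[v]
        candidates = {state.assign[nb] for nb in state.graph.neighbors(v)}
        candidates.add(max(state.S.keys(), default=0) + 1)  # fresh singleton
        candidates.discard(src)
        best_L = current_L
        best_target = src
        for target in sorted(candidates):
            state.move_node(v, target)
            L = state.codelength()
            if L < best_L - 1e-13:
                best_L = L
                best_target = target
            state.move_node(v, src)
        if best_target != src:
            state.move_node(v, best_target)
            current_L = best_L
            improved = True
    return improved


def _merge_moves(state: _MapState) -> bool:
    """Try merging adjacent module pairs; returns True on improvement."""
    improved = False
    while True:
        pairs: set[tuple[int, int]] = set()
        for a, b in state.graph.edges:
            ma, mb = state.assign[a], state.assign[b]
            if ma != mb:
                pairs.add((min(ma, mb), max(ma, mb)))
        if not pairs:
            return improved
        base_L = state.codelength()
        best = None
        for ma, mb in sorted(pairs):
            members = [v for v, m in state.assign.items() if m == mb]
            for v in members:
                state.move_node(v, ma)
            L = state.codelength()
            if L < base_L - 1e-13 and (best is None or L < best[0]):
                best = (L, ma, mb)
            for v in members:
                state.move_node(v, mb)
        if best is None:
            return improved
        _, ma, mb = best
        for v in [v for v, m in state.assign.items() if m == mb]:
            state.move_node(v, ma)
        improved = True


def detect_communities(
    network: EnzymeNetwork | nx.Graph,
    flows: NodeFlows | None = None,
    n_iterations: int = 1000,
    seed: int = 0,
    damping: float = 1.0,
) -> CommunityPartition:
    """Minimum-codelength partition found over ``n_iterations`` restarts.

    Each restart begins from singletons, sweeps shuffled single-node moves
    to convergence, then greedily merges adjacent modules; the best
    codelength over all restarts wins.  Deterministic given ``seed``.
    """
    graph = network.projection if isinstance(network, EnzymeNetwork) else network
    if graph.number_of_edges() == 0:
        raise ValueError("projection graph has no edges")
    if flows is None:
        flows = node_flows(graph, damping=damping)
    nodes = sorted(graph.nodes)
    rng = np.random.default_rng(seed)

    best_assign: dict[str, int] | None = None
    best_L = math.inf
    for _ in range(n_iterations):
        order = list(nodes)
        rng.shuffle(order)
        state = _MapState(graph, flows.f, flows.damping, {v: i for i, v in enumerate(nodes)})
        while True:
            moved = _local_moves(state, order, rng)
            merged = _merge_moves(state)
            if not moved and not merged:
                break
        L = state.codelength()
        if L < best_L - 1e-13:
            best_L = L
            best_assign = dict(state.assign)

    assert best_assign is not None
    # canonical labels: communities numbered by their smallest member
    by_module: dict[int, list[str]] = {}
    for v, m in best_assign.items():
        by_module.setdefault(m, []).append(v)
    ordered = sorted(by_module.values(), key=lambda ms: min(ms))
    relabel = {v: i for i, members in enumerate(ordered) for v in members}
    return CommunityPartition(assignment=relabel, codelength=best_L)
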