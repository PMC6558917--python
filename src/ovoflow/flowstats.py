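"""Normalized intensity flow and permutation Z-scores for network entities.

The central statistic for a member set M of enzyme nodes is the normalized
intensity flow

    f_N = ( sum_{k in M} w_k I_k f_k ) / sqrt( sum_{k in M} w_k )

where f_k is the node's random-walk flow, w_k the number of metabolites the
enzyme catalyses (bipartite degree; set to 1 for metabolite scoring), and
I_k the transcript intensity (1 when scoring without expression data).
The sqrt-of-weights denominator makes communities of different sizes
comparable.

Significance is assessed against a permutation null: the same statistic on
``n_perm`` random member sets of equal size drawn without replacement from
the whole network's (w, I, f) triples, summarised as

    z = (f_N - mu) / sigma.

Entity tables are produced for communities x pathways, single genes, and
metabolites, with deterministic seeding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import CommunityPartition, EnzymeNetwork, NodeFlows

__all__ = [
    "IntensityVector",
    "normalized_flow",
    "permutation_null",
    "zscore",
    "score_communities",
    "score_pathways",
    "score_genes",
    "score_metabolites",
    "top_entities",
]

SIGMA_GUARD = 1e-12


@dataclass
class IntensityVector:
    """Per-node transcript intensities; missing nodes default to 1.0."""

    I: dict[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.I.items() if v < 0}
        if bad:
            raise ValueError(f"negative intensities: {bad}")

    def get(self, node: str) -> float:
        return self.I.get(node, 1.0)

    @classmethod
    def ones(cls) -> "IntensityVector":
        return cls(I={})

    @classmethod
    def from_table(cls, expression: pd.DataFrame) -> "IntensityVector":
        """Mean intensity per gene across rows (probe collapsing by mean)."""
        grouped = expression.groupby("gene")["intensity"].mean()
        return cls(I=grouped.to_dict())


def normalized_flow(
    members: Sequence[str],
    w: Mapping[str, float],
    I: IntensityVector | Mapping[str, float],
    f: NodeFlows | Mapping[str, float],
) -> float:
    """Normalized intensity flow of a member set (0 for the empty set)."""
    if len(members) == 0:
        return 0.0
    get_I = I.get if isinstance(I, IntensityVector) else lambda k: I[k]
    fmap = f.f if isinstance(f, NodeFlows) else f
    num = 0.0
    den = 0.0
    for k in members:
        wk = float(w[k])
        Ik = float(get_I(k))
        if wk < 0 or Ik < 0:
            raise ValueError(f"negative weight or intensity for node {k!r}")
        num += wk * Ik * float(fmap[k])
        den += wk
    if den == 0.0:
        return 0.0
    return num / math.sqrt(den)


def _pool_arrays(
    pool: Sequence[tuple[float, float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pool, dtype=float)  # columns: w, I, f
    if (arr[:, :2] < 0).any():
        raise ValueError("pool contains negative weights or intensities")
    return arr[:, 0], arr[:, 0] * arr[:, 1] * arr[:, 2]


def permutation_null(
    pool: Sequence[tuple[float, float, float]],
    size: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and sd of the normalized flow over random equal-size member sets.

    Each of the ``n_perm`` samples draws ``size`` (w, I, f) triples without
    replacement from the pool.  Deterministic given ``seed``.
    """
    if size > len(pool):
        raise ValueError(f"sample size {size} exceeds pool size {len(pool)}")
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    w, wif = _pool_arrays(pool)
    rng = np.random.default_rng(seed)
    npool = len(pool)
    # vectorised sampling without replacement: argpartition of random keys
    keys = rng.random((n_perm, npool))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    num = wif[idx].sum(axis=1)
    den = np.sqrt(w[idx].sum(axis=1))
    vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(vals.mean()), float(vals.std(ddof=0))


def zscore(f_p: float, mu: float, sigma: float) -> tuple[float, bool]:
    """(z, defined) with a guard against a degenerate permutation sd."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma < SIGMA_GUARD:
        return (0.0 if abs(f_p - mu) < SIGMA_GUARD else math.nan, False)
    return ((f_p - mu) / sigma, True)


# ---------------------------------------------------------------------------
# Entity scoring tables
# ---------------------------------------------------------------------------

_RESULT_COLS = [
    "entity", "community", "f_p", "mu", "sigma", "z", "z_defined",
    "n_members", "n_permutations",
]


def _network_pool(
    network: EnzymeNetwork,
    flows: NodeFlows,
    intensity: IntensityVector,
    unit_w: bool = False,
) -> tuple[list[str], list[tuple[float, float, float]]]:
    w = network.w
    nodes = sorted(network.enzymes)
    pool = [
        (1.0 if unit_w else float(w[g]), intensity.get(g), flows.f.get(g, 0.0))
        for g in nodes
    ]
    return nodes, pool


def _score_member_sets(
    member_sets: dict[tuple, list[str]],
    network: EnzymeNetwork,
    flows: NodeFlows,
    intensity: IntensityVector,
    n_perm: int,
    seed: int,
    unit_w: bool = False,
) -> pd.DataFrame:
    nodes, pool = _network_pool(network, flows, intensity, unit_w=unit_w)
    node_pos = {g: i for i, g in enumerate(nodes)}
    w_map = {g: pool[node_pos[g]][0] for g in nodes}
    null_cache: dict[int, tuple[float, float]] = {}
    rows = []
    for key in sorted(member_sets):
        members = member_sets[key]
        entity, community = key if len(key) == 2 else (key[0], None)
        f_p = normalized_flow(members, w_map, intensity, flows)
        size = len(members)
        if size not in null_cache:
            null_cache[size] = permutation_null(pool, size, n_perm=n_perm, seed=seed)
        mu, sigma = null_cache[size]
        z, defined = zscore(f_p, mu, sigma)
        rows.append(
            {
                "entity": entity,
                "community": community,
                "f_p": f_p,
                "mu": mu,
                "sigma": sigma,
                "z": z,
                "z_defined": defined,
                "n_members": size,
                "n_permutations": n_perm,
            }
        )
    return pd.DataFrame(rows, columns=_RESULT_COLS)


def score_communities(
    network: EnzymeNetwork,
    flows: NodeFlows,
    partition: CommunityPartition,
    intensity: IntensityVector | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalized flow and Z-score per community."""
    intensity = intensity or IntensityVector.ones()
    member_sets = {
        (c,): partition.members(c) for c in sorted(set(partition.assignment.values()))
    }
    member_sets = {k: [g for g in v if g in network.bipartite] for k, v in member_sets.items()}
    member_sets = {k: v for k, v in member_sets.items() if v}
    return _score_member_sets(member_sets, network, flows, intensity, n_perm, seed)


def gene_pathways(model, network: EnzymeNetwork) -> dict[str, frozenset[str]]:
    """Map gene -> subsystems of the reactions it catalyses."""
    out: dict[str, set[str]] = {}
    for r in model.reactions:
        if not r.subsystem:
            continue
        for g in r.genes:
            if g in network.bipartite:
                out.setdefault(g, set()).add(r.subsystem)
    return {g: frozenset(s) for g, s in out.items()}


def score_pathways(
    network: EnzymeNetwork,
    flows: NodeFlows,
    partition: CommunityPartition,
    pathway_of_gene: Mapping[str, frozenset[str] | set[str]],
    intensity: IntensityVector | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per (community, pathway) enrichment of normalized flow.

    Members of a scored set are the community's genes annotated to the
    pathway; the null resamples (w, I, f) triples of equal count from the
    whole network.
    """
    intensity = intensity or IntensityVector.ones()
    member_sets: dict[tuple, list[str]] = {}
    for g, comm in partition.assignment.items():
        if g not in network.bipartite:
            continue
        for pw in pathway_of_gene.get(g, ()):  # genes may span several pathways
            member_sets.setdefault((pw, comm), []).append(g)
    member_sets = {k: sorted(v) for k, v in member_sets.items()}
    if not member_sets:
        raise ValueError("pathway annotation covers no gene in the partition")
    return _score_member_sets(member_sets, network, flows, intensity, n_perm, seed)


def score_genes(
    network: EnzymeNetwork,
    flows: NodeFlows,
    intensity: IntensityVector | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-gene scores: member set = {gene}, weighted by its w_k."""
    intensity = intensity or IntensityVector.ones()
    member_sets = {(g,): [g] for g in network.enzymes}
    return _score_member_sets(member_sets, network, flows, intensity, n_perm, seed)


def score_metabolites(
    network: EnzymeNetwork,
    flows: NodeFlows,
    intensity: IntensityVector | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Metabolite scores from the flows of their catalysing enzymes (w_k = 1).

    Isolated metabolites (no catalysing enzyme) are skipped.
    """
    intensity = intensity or IntensityVector.ones()
    member_sets: dict[tuple, list[str]] = {}
    for met in network.metabolite_nodes:
        enz = sorted(network.enzymes_of_metabolite(met))
        if enz:
            member_sets[(met,)] = enz
    return _score_member_sets(
        member_sets, network, flows, intensity, n_perm, seed, unit_w=True
    )


def top_entities(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k rows by z (descending), ties broken by f_p then entity id."""
    if len(table) == 0:
        raise ValueError("cannot rank an empty result table")
    ranked = table.sort_values(
        by=["z", "f_p", "entity"], ascending=[False, False, True], kind="mergesort"
    )
    out = ranked.head(k).copy()
    out["rank"] = range(1, len(out) + 1)
    return out.reset_index(drop=True)
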