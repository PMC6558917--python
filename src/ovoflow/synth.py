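"""Synthetic inputs with planted ground truth for every pipeline stage.

Real follicle studies start from genome-scale reconstructions and four
microarray series; nothing of that scale is needed to exercise the
machinery.  The generators here produce small, fully determined stand-ins:

* a hand-built pair of somatic/oocyte toy models sharing plasma exchanges
  (glucose, pyruvate, lactate, oxygen) whose LP optima are hand-solvable;
* random mass-balanced networks that are flux-consistent by construction
  (chains from uptake to export plus cross arcs between reachable
  metabolites), with optional orphan reactions that are blocked by
  construction — the ground-truth blocked set is returned, never
  recomputed;
* stochastic block-model graphs with planted community labels;
* expression tables with planted oocyte-specific genes (significant at the
  standard thresholds and diluted in the whole-follicle contrast) and a
  planted high-intensity "hot" pathway.

Every generator is bit-reproducible given its seed.  Noise model: a
multiplicative log-normal jitter (``noise_sigma`` on the log scale) on
fold changes and intensities; null p-values are uniform, planted p-values
uniform below the significance cutoff.  These are documented defaults of
this package, not measured microarray properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .model import MetabolicModel, Metabolite, Reaction, parse_gpr

__all__ = [
    "GeneratorSpec",
    "RandomModelResult",
    "toy_follicle_model",
    "random_consistent_model",
    "planted_partition_graph",
    "synthetic_expression",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Sizes, effect sizes and graph parameters for the generators."""

    seed: int = 0
    n_genes: int = 60
    n_reactions: int = 30
    n_stages: int = 2
    n_orphans: int = 0
    # expression effects
    hot_multiplier: float = 10.0
    planted_fc: float = 4.0
    planted_p_max: float = 0.008
    dilution_base: float = 0.95
    noise_sigma: float = 0.0
    frac_oocyte: float = 0.15
    frac_both: float = 0.10
    # planted-partition graph
    k_communities: int = 3
    block_size: int = 20
    p_in: float = 0.9
    p_out: float = 0.05

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_out, self.frac_oocyte, self.frac_both):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        if self.n_reactions < 3 or self.n_genes < 1:
            raise ValueError("sizes must allow at least a minimal network")


# ---------------------------------------------------------------------------
# Toy coupled follicle fixture
# ---------------------------------------------------------------------------


def _ex(met: str, lb: float, ub: float) -> Reaction:
    return Reaction(id=f"EX_{met}", metabolites={met: -1.0}, lower_bound=lb, upper_bound=ub)


def toy_follicle_model() -> tuple[MetabolicModel, MetabolicModel, dict[str, float]]:
    """Hand-built somatic and oocyte models plus a plasma medium.

    The somatic cell converts glucose to pyruvate (2 pyr per glc) and can
    respire or ferment it; the oocyte burns pyruvate (or glycolytic
    pyruvate) with oxygen into a biomass sink.  All optima are hand-
    checkable: somatic pyruvate secretion maxes at 10 for glucose uptake
    <= 5.
    """
    def met(mid: str) -> Metabolite:
        comp = mid.rsplit("_", 1)[1]
        return Metabolite(id=mid, name=mid, compartment=comp)

    som_mets = [met(m) for m in (
        "glc_e", "glc_c", "pyr_e", "pyr_c", "lac_e", "lac_c",
        "o2_e", "o2_c", "co2_e", "co2_c",
    )]
    som_rxns = [
        _ex("glc_e", -5.0, 0.0),
        _ex("o2_e", -10.0, 0.0),
        _ex("pyr_e", -1000.0, 1000.0),
        _ex("lac_e", 0.0, 1000.0),
        _ex("co2_e", 0.0, 1000.0),
        Reaction("T_glc", {"glc_e": -1, "glc_c": 1}, 0, 1000, subsystem="Transport",
                 gene_sets=parse_gpr("gTglc")),
        Reaction("T_o2", {"o2_e": -1, "o2_c": 1}, 0, 1000, subsystem="Transport",
                 gene_sets=parse_gpr("gTo2")),
        Reaction("T_pyr", {"pyr_c": -1, "pyr_e": 1}, -1000, 1000, subsystem="Transport",
                 gene_sets=parse_gpr("gTpyr")),
        Reaction("T_lac", {"lac_c": -1, "lac_e": 1}, 0, 1000, subsystem="Transport",
                 gene_sets=parse_gpr("gTlac")),
        Reaction("T_co2", {"co2_c": -1, "co2_e": 1}, 0, 1000, subsystem="Transport",
                 gene_sets=parse_gpr("gTco2")),
        Reaction("GLY", {"glc_c": -1, "pyr_c": 2}, 0, 1000, subsystem="Glycolysis",
                 gene_sets=parse_gpr("gGly1 or gGly2")),
        Reaction("LDH", {"pyr_c": -1, "lac_c": 1}, 0, 1000, subsystem="Glycolysis",
                 gene_sets=parse_gpr("gLdh")),
        Reaction("RESP", {"pyr_c": -1, "o2_c": -1, "co2_c": 1}, 0, 1000,
                 subsystem="OxPhos", gene_sets=parse_gpr("gResp1 and gResp2")),
        Reaction("BIOMASS_SOM", {"glc_c": -0.5, "o2_c": -0.5}, 0, 1000,
                 subsystem="Biomass"),
    ]
    somatic = MetabolicModel(metabolites=som_mets, reactions=som_rxns, id="toy_somatic")

    oo_mets = [met(m) for m in (
        "glc_e", "glc_c", "pyr_e", "pyr_c", "lac_e", "lac_c", "o2_e", "o2_c",
    )]
    oo_rxns = [
        _ex("glc_e", -1000.0, 0.0),
        _ex("o2_e", -1000.0, 0.0),
        _ex("pyr_e", -1000.0, 1000.0),
        _ex("lac_e", 0.0, 1000.0),
        Reaction("T_glc", {"glc_e": -1, "glc_c": 1}, 0, 1000, subsystem="Transport",
                 gene_sets=parse_gpr("gTglc")),
        Reaction("T_o2", {"o2_e": -1, "o2_c": 1}, 0, 1000, subsystem="Transport",
                 gene_sets=parse_gpr("gTo2")),
        Reaction("T_pyr", {"pyr_e": -1, "pyr_c": 1}, 0, 1000, subsystem="Transport",
                 gene_sets=parse_gpr("gTpyr")),
        Reaction("T_lac", {"lac_c": -1, "lac_e": 1}, 0, 1000, subsystem="Transport",
                 gene_sets=parse_gpr("gTlac")),
        Reaction("GLY_O", {"glc_c": -1, "pyr_c": 2}, 0, 1000, subsystem="Glycolysis",
                 gene_sets=parse_gpr("gGly1")),
        Reaction("LDH_O", {"pyr_c": -1, "lac_c": 1}, 0, 1000, subsystem="Glycolysis",
                 gene_sets=parse_gpr("gLdh")),
        Reaction("BIOMASS_OOC", {"pyr_c": -1, "o2_c": -1}, 0, 1000,
                 subsystem="Biomass"),
    ]
    oocyte = MetabolicModel(metabolites=oo_mets, reactions=oo_rxns, id="toy_oocyte")

    plasma = {"glc_e": 5.0, "o2_e": 10.0, "pyr_e": 0.0, "lac_e": 0.0}
    return somatic, oocyte, plasma


# ---------------------------------------------------------------------------
# Random consistent models
# ---------------------------------------------------------------------------


@dataclass
class RandomModelResult:
    model: MetabolicModel
    blocked_ground_truth: frozenset[str]  # injected orphan reaction ids
    chain_of_reaction: dict[str, int] = field(default_factory=dict)


def random_consistent_model(spec: GeneratorSpec) -> RandomModelResult:
    """Random network that is flux-consistent by construction.

    Backbone: parallel chains uptake -> m1 -> ... -> mk -> export; every
    chain metabolite is then both producible from an uptake and drainable
    to an export, so any extra arc between chain metabolites (added until
    the reaction budget is met, occasionally reversible) also carries flux.
    ``spec.n_orphans`` reactions producing a never-consumed metabolite are
    appended; exactly these are blocked.
    """
    rng = np.random.default_rng(spec.seed)
    budget = spec.n_reactions - spec.n_orphans
    if budget < 3:
        raise ValueError("n_reactions too small for the requested orphans")

    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    live: list[str] = []  # chain metabolites (producible and drainable)
    chain_of: dict[str, int] = {}
    genes = [f"g{i:03d}" for i in range(spec.n_genes)]

    def add_met(mid: str, comp: str) -> str:
        mets.append(Metabolite(id=mid, name=mid, compartment=comp))
        return mid

    def random_gpr() -> tuple:
        form = rng.integers(0, 3)
        picks = rng.choice(len(genes), size=2, replace=False)
        a, b = genes[picks[0]], genes[picks[1]]
        if form == 0:
            return parse_gpr(a)
        if form == 1:
            return parse_gpr(f"{a} or {b}")
        return parse_gpr(f"{a} and {b}")

    chain_idx = 0
    used = 0
    while used + 4 <= budget:
        length = int(rng.integers(1, 4))  # internal conversions
        if used + length + 3 > budget:
            length = max(1, budget - used - 3)
        src = add_met(f"m{len(mets):03d}_e", "e")
        rxns.append(_ex(src, -10.0, 0.0))
        prev = add_met(f"m{len(mets):03d}_c", "c")
        rxns.append(
            Reaction(f"R{len(rxns):03d}_upt", {src: -1, prev: 1}, 0, 1000,
                     subsystem=f"PW{chain_idx}", gene_sets=random_gpr())
        )
        live.append(prev)
        chain_of[prev] = chain_idx
        for _ in range(length - 1):
            nxt = add_met(f"m{len(mets):03d}_c", "c")
            rxns.append(
                Reaction(f"R{len(rxns):03d}_cnv", {prev: -1, nxt: 1}, 0, 1000,
                         subsystem=f"PW{chain_idx}", gene_sets=random_gpr())
            )
            live.append(nxt)
            chain_of[nxt] = chain_idx
            prev = nxt
        out = add_met(f"m{len(mets):03d}_e", "e")
        rxns.append(
            Reaction(f"R{len(rxns):03d}_sec", {prev: -1, out: 1}, 0, 1000,
                     subsystem=f"PW{chain_idx}", gene_sets=random_gpr())
        )
        rxns.append(_ex(out, 0.0, 1000.0))
        used += length + 3  # conversions + two exchanges count toward budget
        chain_idx += 1
        if chain_idx >= 6:
            break

    # cross arcs between live metabolites, always able to carry flux
    while used < budget and len(live) >= 2:
        picks = rng.choice(len(live), size=2, replace=False)
        a, b = live[picks[0]], live[picks[1]]
        reversible = bool(rng.random() < 0.3)
        rxns.append(
            Reaction(
                f"R{len(rxns):03d}_arc",
                {a: -1, b: 1},
                -1000 if reversible else 0,
                1000,
                subsystem=f"PW{int(rng.integers(0, max(chain_idx, 1)))}",
                gene_sets=random_gpr(),
            )
        )
        used += 1

    blocked: set[str] = set()
    for i in range(spec.n_orphans):
        src = live[int(rng.integers(0, len(live)))]
        orphan = add_met(f"orph{i}_c", "c")
        rid = f"R{len(rxns):03d}_orphan"
        rxns.append(
            Reaction(rid, {src: -1, orphan: 1}, 0, 1000,
                     subsystem="Orphan", gene_sets=random_gpr())
        )
        blocked.add(rid)

    model = MetabolicModel(metabolites=mets, reactions=rxns, id=f"rand{spec.seed}")
    return RandomModelResult(
        model=model,
        blocked_ground_truth=frozenset(blocked),
        chain_of_reaction={r.id: chain_of.get(next(iter(r.metabolites)), -1) for r in rxns},
    )


# ---------------------------------------------------------------------------
# Planted-partition graphs
# ---------------------------------------------------------------------------


def planted_partition_graph(spec: GeneratorSpec) -> tuple[nx.Graph, dict[int, int]]:
    """Stochastic block model with ground-truth block labels."""
    if spec.k_communities < 2:
        raise ValueError("need at least two communities")
    if not spec.p_in > spec.p_out:
        raise ValueError("planted structure requires p_in > p_out")
    g = nx.planted_partition_graph(
        spec.k_communities, spec.block_size, spec.p_in, spec.p_out,
        seed=int(spec.seed),
    )
    labels = {node: node // spec.block_size for node in g.nodes}
    for _, _, d in g.edges(data=True):
        d["weight"] = 1
    return g, labels


# ---------------------------------------------------------------------------
# Expression tables with planted structure
# ---------------------------------------------------------------------------

ARRAYS = ("oocyte", "follicle", "cumulus", "mural", "cumulus_competence")


def synthetic_expression(
    spec: GeneratorSpec,
    model: MetabolicModel,
    hot_subsystem: str | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, object]]:
    """Per-array expression tables with planted oocyte/shared genes.

    Returns (tables, truth).  ``tables[array]`` has columns gene,
    intensity, fold_change, fdr_p, detected; the follicle table's fold
    change is the primary -> two-layered-secondary dilution contrast.
    ``truth`` carries the planted oocyte_only/both gene sets and the hot
    pathway genes; downstream code must treat it as ground truth, never
    recompute it.
    """
    rng = np.random.default_rng(spec.seed)
    genes = sorted(model.genes)
    if not genes:
        raise ValueError("model has no genes to express")
    n = len(genes)
    sig = spec.noise_sigma

    n_ooc = int(round(spec.frac_oocyte * n))
    n_both = int(round(spec.frac_both * n))
    perm = rng.permutation(n)
    oocyte_only = {genes[i] for i in perm[:n_ooc]}
    both = {genes[i] for i in perm[n_ooc:n_ooc + n_both]}

    subsystems = sorted({r.subsystem for r in model.reactions if r.subsystem})
    if hot_subsystem is None and subsystems:
        hot_subsystem = subsystems[int(rng.integers(0, len(subsystems)))]
    hot_genes = {
        g
        for r in model.reactions
        if r.subsystem == hot_subsystem
        for g in r.genes
    }

    def jitter(size: int, sigma: float) -> np.ndarray:
        if sigma == 0.0:
            return np.ones(size)
        return np.exp(rng.normal(0.0, sigma, size=size))

    def base_intensity() -> np.ndarray:
        vals = np.exp(rng.normal(np.log(100.0), 1.0, size=n))
        return vals

    tables: dict[str, pd.DataFrame] = {}
    for array in ARRAYS[: max(2, min(len(ARRAYS), 5))]:
        intensity = base_intensity()
        hot_mask = np.array([g in hot_genes for g in genes])
        intensity = intensity * np.where(hot_mask, spec.hot_multiplier, 1.0)

        fc = np.exp(rng.normal(0.0, 0.3, size=n))  # null fold changes
        p = rng.uniform(0.02, 1.0, size=n)
        if array == "oocyte":
            planted = np.array([g in oocyte_only or g in both for g in genes])
            fc = np.where(planted, spec.planted_fc * jitter(n, sig), fc)
            p = np.where(planted, rng.uniform(2e-4, spec.planted_p_max, size=n), p)
        elif array == "follicle":
            ooc_mask = np.array([g in oocyte_only for g in genes])
            both_mask = np.array([g in both for g in genes])
            # oocyte transcripts are diluted by granulosa proliferation;
            # shared transcripts track it instead
            fc = np.where(ooc_mask, spec.dilution_base * jitter(n, sig / 4 if sig else 0.0), fc)
            fc = np.where(both_mask, 2.0 * jitter(n, sig / 4 if sig else 0.0), fc)
        detected = rng.random(n) < 0.95 if sig > 0 else np.ones(n, dtype=bool)
        tables[array] = pd.DataFrame(
            {
                "gene": genes,
                "intensity": intensity,
                "fold_change": fc,
                "fdr_p": p,
                "detected": detected,
            }
        )

    truth: dict[str, object] = {
        "oocyte_only": frozenset(oocyte_only),
        "both": frozenset(both),
        "hot_subsystem": hot_subsystem,
        "hot_genes": frozenset(hot_genes),
    }
    return tables, truth
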