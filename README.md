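# ovoflow

Constraint-based metabolic modelling of ovarian follicle development.

During folliculogenesis the oocyte matures inside proliferating layers of
somatic cells (granulosa, theca, and — after antrum formation — cumulus and
mural granulosa).  The two compartments feed each other: somatic cells
convert plasma glucose into pyruvate and other intermediates that the
oocyte, which glycolyses poorly, depends on.  `ovoflow` provides the
computational machinery to study this coupled system from transcriptomic
data and a genome-scale metabolic reconstruction:

* **Model core** — a `MetabolicModel` container (stoichiometry `S`, flux
  bounds, gene–protein–reaction rules in disjunctive normal form,
  subsystems) with SBML L3/FBC-v2 and plain-TSV I/O, plus a harness that
  scores a model against a battery of metabolic-function tests
  (maximise an objective on a defined medium; pass iff |optimum| ≥ θ).
* **Consistency & extraction** — flux variability analysis over
  `{v : S·v = 0, lb ≤ v ≤ ub}`, blocked-reaction/dead-end detection, and
  FASTCORE-style context-specific extraction: given a core of reactions
  whose GPRs are satisfied by expressed genes, alternate LP7 (push core
  reactions to flux ≥ ε) and LP10 (minimise the scaled L1 penalty on
  non-core flux) to obtain a near-minimal flux-consistent subnetwork
  containing the core.  An optional `polish` local search tightens the
  non-core count on small models.
* **Enzyme network & communities** — the enzyme–metabolite bipartite graph
  (enzyme `k` linked to the metabolites it catalyses, `w_k` = its bipartite
  degree), its one-mode projection weighted by shared-metabolite counts,
  random-walk node flows `f_k`, and community detection by two-level
  map-equation minimisation
  `L(M) = q·H(Q) + Σᵢ pᵢ·H(Pᵢ)` with shuffled-restart local search.
* **Flow statistics** — the normalized intensity flow of a member set
  (community, pathway, gene, or metabolite)

      f_N = Σₖ wₖ·Iₖ·fₖ / sqrt(Σₖ wₖ)

  where `I_k` is the transcript intensity (1 without expression data), and
  permutation Z-scores `z = (f_N − μ)/σ` against 1000 equal-size random
  member sets drawn from the whole network; top-k ranking.
* **Segregation** — assignment of transcripts to oocyte / somatic / shared
  compartments: oocyte-only iff significant in the oocyte arrays
  (FC ≥ 2.5, FDR ≤ 0.01) *and* diluted (FC < 1.05) in the whole-follicle
  primary → two-layered-secondary contrast; plus cell-type-specific calls
  across arrays.
* **Histology** — closed-form cell counts from sections:
  `r_A = sqrt(A_A/π)`, density `ρ = n/(f·π·(r²_FwoT − r²_O − A_A))`,
  count `n_G = (4/3)·π·ρ·(r³_FwoT − r³_O − r³_A)`.
* **Coupled FBA** — stage-specific objectives, measured-flux constraints,
  and iterative somatic→oocyte coupling: somatic uptake is scaled by
  bisection until pyruvate secretion matches its measured target, somatic
  net exchange (× cells per oocyte) is added to the plasma medium of the
  oocyte, and secreted/consumed metabolites are classified per stage and
  cell type.
* **Synthetic data** — generators for every input class with planted
  ground truth (blocked reactions, community labels, oocyte-specific
  genes, hot pathways), so the whole pipeline runs and is tested without
  any external download.

Exchange fluxes follow the standard convention: negative = uptake,
positive = secretion (`met_e ⇌ ∅`).  Flux units are mmol·gDW⁻¹·h⁻¹,
lengths µm, codelengths bits.

## Worked example

The built-in toy follicle: a somatic cell that converts glucose to
pyruvate (2 pyr per glc, uptake capped at 5) coupled to an oocyte that
burns pyruvate with oxygen, at 50 somatic cells per oocyte, with somatic
pyruvate secretion constrained to a measured 2 mmol·gDW⁻¹·h⁻¹:

```python
from ovoflow import (
    toy_follicle_model, StageConfig, couple_cells, find_blocked,
)

somatic, oocyte, plasma = toy_follicle_model()
print("blocked reactions:", sorted(find_blocked(somatic).blocked_reactions))

cfg = StageConfig(
    stage="primary",
    somatic_objective={"EX_pyr_e": 1.0},
    oocyte_objective={"BIOMASS_OOC": 1.0, "EX_pyr_e": -1.0},
    pyruvate_exchange="EX_pyr_e",
    oxygen_exchange="EX_o2_e",
)
result = couple_cells(somatic, oocyte, cfg, cell_ratio=50.0,
                      plasma=plasma, pyruvate_target=2.0)
print(f"uptake multiplier: {result.uptake_multiplier:.3f}")
print(f"somatic pyruvate secretion: {result.somatic.fluxes['EX_pyr_e']:.3f}")
print(f"oocyte pyruvate availability: {result.oocyte_medium['pyr_e']:.1f}")
print(result.exchanged.to_string(index=False))
```

prints

```
blocked reactions: []
uptake multiplier: 0.200
somatic pyruvate secretion: 2.000
oocyte pyruvate availability: 100.0
  stage metabolite cell_type direction        flux
primary      glc_e   somatic  consumed   -1.000000
primary      pyr_e   somatic  secreted    2.000000
primary       o2_e    oocyte  consumed  -10.000000
primary      pyr_e    oocyte  consumed -100.000024
primary      lac_e    oocyte  secreted   90.000024
```

Reading it: bisection finds that 20 % of the plasma allowance (1 glc)
suffices for the 2-pyruvate target; the oocyte sees
`plasma (0) + 50 × 2 = 100` pyruvate, consumes it, respires what its
oxygen bound allows and exports the rest as lactate.

## Command line

`ovoflow synth --seed 1 --out fixtures` writes a complete synthetic input
tree (model TSVs, per-array expression, histology, plasma, stage configs,
`config.yaml`); `ovoflow run -c fixtures/config.yaml` then executes the
whole pipeline (consistency → sub-models → communities → scores →
segregation → cell counts → coupled FBA) and writes TSV tables plus a
`manifest.json` recording seeds and parameters.  The individual
subcommands (`extract`, `communities`, `score`, `segregate`, `cellcount`,
`couple`) map one-to-one onto the library operations.

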