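# Methods

This note documents the models, numerical choices and limitations behind
`ovoflow`, in the order the pipeline applies them.

## Constraint-based core

A metabolic model is the pair (S, bounds): a sparse stoichiometric matrix
over metabolites × reactions and per-reaction flux bounds in
mmol·gDW⁻¹·h⁻¹.  All analyses operate on the steady-state polytope
{v : S·v = 0, lb ≤ v ≤ ub}.  Exchange pseudo-reactions are written
`met_e ⇌ ∅` with coefficient −1, so uptake is negative flux and secretion
positive; every sign rule downstream (media, coupling, secreted/consumed
calls) derives from this single convention.  GPR rules are stored in
disjunctive normal form — a tuple of gene sets, each set an enzyme complex,
the tuple the isoenzyme alternatives — which makes expression evaluation
(`any conjunction fully expressed`) and gene→reaction mapping trivial.

LPs are solved with HiGHS through `scipy.optimize.linprog`.  The
metabolic-function harness closes every exchange uptake, opens the uptakes
listed in the test's medium, optimises the test's objective reaction and
passes the test iff |optimum| ≥ θ with θ = 10⁻⁶ flux units by default; the
feasibility threshold is a package choice, exposed per test.  Infeasible
LPs are recorded as failures with a reason, never raised, so a battery
always yields a complete report.

## Consistency and context-specific extraction

A reaction is *blocked* when its FVA range stays inside (−ε, ε) with
ε = 10⁻⁴ (the convention of the original consistency literature; exposed
in every API and in the pipeline config).  `find_blocked` first runs an
LP7-style sweep (maximise the number of reactions pushed to ≥ ε, once
forward and once with reversible directions mirrored), which certifies
most reactions as unblocked in two solver calls, then settles the
remainder with per-reaction max/min LPs.  Dead-end metabolites are derived
from the unblocked set: a metabolite lacking an active producer or an
active consumer (reversible reactions count as both).

Context-specific extraction follows the two-LP alternation of the FASTCORE
family: LP7 maximises the count of unsatisfied core reactions carrying
flux ≥ ε; LP10 minimises an L1 penalty on non-core flux while pinning the
newly satisfied core at ε, with bounds scaled by 10⁵ for numerical
headroom and support read at 0.99 ε in the scaled space.  Reversible
reactions are handled by the direction-flipping scheme of the original
algorithm (bound mirror + column negation), not by network splitting;
reverse-only reactions (ub ≤ 0) are canonically flipped up front.  Results
are deterministic: ties among alternate LP optima are resolved by the
solver's deterministic pivoting and reaction index order.

The plain algorithm is near-minimal, not minimal: LP10's L1 geometry can
prefer a route that is cheaper in total flux but uses more reactions, and
the greedy union over iterations never revisits a commitment.  On small
instances we observed such off-by-one/two excesses in roughly one case in
eight.  `fastcore(..., polish=True)` therefore adds a cardinality local
search: (i) cascade pruning — remove one non-core reaction together with
everything its removal blocks, accept if the core survives and the set
shrinks; (ii) single-addition moves — add one outside reaction and re-run
the cascade prune, which lets a newly available shortcut retire a longer
route.  Both moves preserve flux consistency and core containment by
construction and strictly decrease the set size, so the search terminates.
Its cost is O(|reactions|) consistency checks per accepted move, which is
why it is off by default and enabled where the pipeline's desk-scale
models make it cheap.

## Enzyme network and communities

Enzyme nodes are gene ids (isoenzymes are separate nodes; each complex
member contributes its own node), linked to every metabolite of every
non-exchange reaction whose GPR mentions the gene.  Exchange
pseudo-reactions are excluded from graph construction by default.  Two
currency-metabolite controls exist because without them the projection is
a near-clique: an explicit exclusion list (defaults cover H₂O, H⁺,
ATP/ADP/AMP, Pi/PPi, NAD(H), NADP(H), CO₂, O₂ in any compartment, matched
on the id stem) and a metabolite-degree percentile cap.  Both are off
unless requested.  The projection weight between two enzymes is the number
of metabolites they share.

Node flows are the stationary distribution of a teleporting random walk on
the weighted projection (power iteration with a lazy half-step, which
keeps the stationary law but removes periodicity on bipartite-like graphs;
tolerance 10⁻¹⁰ on the L1 residual).  With damping 1 on a connected graph
this is exactly the weighted-degree distribution; the default damping for
flow reporting is 0.85, while community detection uses damping 1 flows so
that hand-checkable degree-proportional identities hold.

Communities minimise the two-level map equation.  With module exit flows
q_i (edge flow leaving the module plus uniform-teleport flow to other
modules) and member visit rates p_α, the codelength is

    L = plogp(Σ q_i) − 2 Σ plogp(q_i) − Σ plogp(p_α)
        + Σ plogp(q_i + Σ_{α∈i} p_α),      plogp(x) = x·log₂x.

The optimiser keeps per-module sufficient statistics (flow mass, teleport
mass, internal edge flow) so a single-node move updates the codelength in
O(degree).  Each restart starts from singletons, sweeps shuffled
single-node moves to convergence, then greedily merges adjacent modules;
the best codelength over `n_iterations` restarts (default 1000, matching
the reference usage of the map-equation tool) wins.  Runs are bit
reproducible given (seed, n_iterations).  Only the flat two-level code is
implemented — the analysis this package supports reports flat communities.

## Normalized flow and permutation Z-scores

The flow score of a member set M is f_N = Σ w_k I_k f_k / sqrt(Σ w_k):
intensity-weighted flow, normalised so communities of different sizes are
comparable (the numerator grows linearly in members, the denominator as
the square root of total weight).  Scoring variants: communities and
pathways use the gene's bipartite degree as w_k; single genes likewise;
metabolites are scored over their catalysing enzymes with w_k = 1.
Intensities for genes measured by several probes/arrays are collapsed by
the mean of detected values; nodes without expression default to I = 1,
which reproduces the expression-free network analysis exactly.

The null model resamples, without replacement, member sets of the same
size from the (w, I, f) triples of the entire network — joint triple
resampling, n_perm = 1000 by default — and standardises:
z = (f_N − μ)/σ, with σ < 10⁻¹² flagged undefined rather than mapped to
±∞.  Note a calibration subtlety: a *fixed* member set under
intensity-label permutation is not exchangeable with this null (its w and
f profile is frozen), so its z is biased and under-dispersed; the
calibration property — mean ≈ 0, sd ≈ 1 — holds for member sets that are
themselves placed at random, which is the relevant null for "is this
pathway's placement surprising".  The test suite checks exactly that
statement.

## Transcript segregation

Thresholds follow the standard microarray practice for this system:
significance at linear fold change ≥ 2.5 with FDR-adjusted p ≤ 0.01 (both
inclusive), dilution strictly below 1.05 in the whole-follicle
primary → two-layered-secondary contrast.  The dilution rule encodes the
biology that oocyte-restricted transcripts are diluted by granulosa
proliferation while shared transcripts track it.  Genes significant in the
oocyte but absent from the dilution contrast are treated as diluted
(no amplification was observed); this edge case is a package choice.
Fold changes are consumed on the linear scale; log2 input must be declared
explicitly (`log2_input=True`), never auto-detected.  Cell-type-specific
calls label a gene `<array>_only` iff it is significant in exactly one
array, else `multi`; unsignificant genes are unlabelled by this step.

## Histology

Sections are modelled as concentric circles; the antral cross-section is
treated as a sphere's equatorial disc, r_A = sqrt(A_A/π).  Slide thickness
defaults to 5 µm.  The density formula as printed in the source geometry,
ρ = f·π·(r²_FwoT − r²_O − A_A)/n, has units of volume per cell; since the
count formula needs cells per volume, the default implementation uses the
reciprocal, with `as_printed=True` returning the printed form unchanged.
Radii are the mean of each follicle's maximal and minimal axes; per-stage
estimates average the per-section counts.  Theca and cumulus counts reuse
the same shell geometry with their own outer/inner radii.

## Coupled somatic–oocyte FBA

Stage configs carry the somatic and oocyte objectives as fixed-weight
linear combinations (weight 1 per term unless configured — no weighting
between biomass and pyruvate terms is claimed), measured exchange-bound
overrides, and the oxygen rule (uptake-only for somatic cells except at
the primordial stage, where it may be freed).  The oocyte's "pyruvate
consumption" objective term is the negative weight on the pyruvate
exchange, i.e. maximising uptake.

Coupling solves the somatic LP on a medium u·plasma, where the scalar
u ∈ [0, 1] is found by bisection so that somatic pyruvate secretion
matches its measured target within tolerance (endpoint checks first, so a
target at the unconstrained optimum converges in one evaluation; a target
above reach returns the closest achievable solution flagged
non-converged with its residual).  The oocyte medium is then
plasma + cell_ratio × somatic net exchange, floored at zero availability,
with cell_ratio taken from the histology estimates.  cell_ratio = 0
reproduces the stand-alone oocyte solve exactly.  Exchange fluxes above
10⁻⁶ are classified secreted, below −10⁻⁶ consumed.

## Synthetic study conditions

The generators exist so every stage has a planted ground truth at desk
scale; they emulate the *structure* of the real inputs, not their
measured distributions:

* Random consistent networks: parallel uptake→conversion→export chains
  plus cross arcs between chain metabolites (30 % reversible).  Every
  chain metabolite is producible and drainable, so cross arcs are
  unblocked by construction; injected orphan-producing reactions are the
  exact blocked set.  Budgets: 30 reactions by default, 10–12 for
  enumeration-scale instances.
* Planted partitions: stochastic block model, 3 blocks × 20 nodes,
  p_in = 0.9, p_out = 0.05.
* Expression: log-normal intensities (median ≈ 100, σ_log = 1), a planted
  hot pathway at 10× intensity, planted oocyte-only genes at fold change
  4.0 with p drawn below 0.008, dilution contrast centred at 0.95, null
  fold changes log-normal (σ = 0.3), null p uniform on [0.02, 1].  The
  noise parameter σ multiplies fold changes as exp(N(0, σ)) (σ/4 on the
  dilution contrast, whose decision boundary at 1.05 is far tighter).
  These distributions are package choices; real arrays carry probe-level
  artefacts, correlated errors and normalisation effects that are
  deliberately out of scope, so passing tests demonstrate algorithmic
  correctness, not microarray realism.
* The toy follicle pair is fixed (not seeded) and fully hand-solvable:
  somatic glycolysis yields 2 pyruvate per glucose with uptake capped at
  5, so maximal secretion is 10; the oocyte biomass sink needs pyruvate
  plus oxygen.

Problem sizes throughout the test-suite and the acceptance script (tens of
reactions, 60-node graphs, 100–1000 permutations/restarts) are chosen so
an end-to-end run takes on the order of a minute while every comparison
against an enumeration or closed-form oracle remains exact.

## Known limitations

* The flow model is an undirected teleporting walk, a stand-in for the
  reference map-equation tool's flow machinery; absolute community counts
  on real reconstructions will differ from published ones even when the
  partition structure agrees.
* Gap filling, reconstruction merging/homology mapping, and differential-
  expression testing are out of scope; the pipeline consumes upstream
  contrast tables (fold change, FDR p) as given.
* The coupled model folds all somatic layers into one compartment; no
  separate theca compartment and no dynamic FBA.
* `polish` scales quadratically with subnetwork size and is meant for
  desk-scale models only.
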