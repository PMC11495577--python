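# Methods

`dielflux` implements a constraint-based analysis of diel (day/night)
multi-tissue plant metabolism: context-specific model extraction from
transcriptomics, assembly of tissue models into a phase-duplicated
whole-plant model, linear-programming phenotype protocols, flux-sampling
differential statistics, and machine learning on flux-capacity features.
Everything is exercised end to end on a synthetic toy plant network so
that the full analysis runs on a laptop with no downloads.

## Constraint-based core

Models are `cobra.Model` objects. Flux balance analysis (FBA) solves
`max c'v s.t. S v = 0, lb <= v <= ub`; parsimonious FBA (pFBA) fixes the
objective at its optimum (or a fraction of it) and minimizes Σ|v|; flux
variability analysis (FVA) reports per-reaction `[min v_r, max v_r]`
subject to the objective staying at ≥ a fraction of its optimum. These
three go through cobra's LP layer (GLPK); the test suite checks them
against independent `scipy.optimize.linprog` (HiGHS) formulations.

Numerical conventions used throughout:

* flux comparison tolerance **1e-6** mmol·gDW⁻¹·h⁻¹; LP feasibility
  **1e-9**; bound cap **1000** for effectively unbounded reactions;
* uptake is a *negative* exchange flux; report layers that print uptake
  tables negate;
* flux-ratio constraints (Rubisco carboxylation:oxygenation **3:1**,
  diel nitrate light:dark **3:2**) are auxiliary equality rows
  `v_a − ratio·v_b = 0` added to the LP, never bound tricks, so they
  hold to 1e-9 in every solution;
* degenerate FVA output (min marginally above max from solver jitter)
  collapses both ends to the midpoint.

Phenotype protocols: *photosynthesis* (photon+CO2 open, sucrose uptake
closed), *photorespiration* (photosynthesis + the 3:1 Rubisco row),
*respiration* (photon closed, sucrose open). Two prediction strategies:
fix growth at 0.11 h⁻¹ and minimize photon/sucrose uptake (with a pFBA
tie-break at the optimal uptake, so the returned distribution is
near-unique), or fix the driver uptake (photon 100, or 300 in diel
models; sucrose 1) and maximize growth followed by pFBA.

## Context-specific extraction

Expression preprocessing averages replicate groups in TPM space, then
applies log2(x+1) (pseudo-count 1 because TPM contains zeros), then maps
gene ids onto model protein ids, dropping unmapped genes with a logged
count.

Activity calling uses the local T2 scheme: global thresholds GL and GU
are the 25th and 75th percentiles of the pooled value distribution (all
genes × all samples, linear-interpolation percentiles); the local
threshold of gene *g* is its own 50th percentile across all samples,
clamped into [GL, GU]. A gene's group-level expression *e* (mean over
the sample group) is active if `e ≥ GU`, inactive if `e < GL`, and
otherwise active iff `e ≥ L(g)`. Ties resolve to active. Activity maps
to reactions through GPR rules with AND = min (complex limited by its
scarcest subunit) and OR = max (isozymes are interchangeable); genes
without a call default to inactive (configurable). Reactions without a
GPR are never core; the biomass pseudo-reaction is always protected.

FASTCC removes reactions unable to carry |v| ≥ ε (default ε = 1e-4) at
steady state; it is implemented by per-reaction LP maximization on an
explicit stoichiometric matrix (HiGHS) and cross-checked against an
independent reference implementation in the tests. FASTCORE alternates
two LPs — LP7 maximizes the number of core reactions with flux ≥ ε, and
LP10 minimizes the L1 flux through non-core reactions while pinning the
covered core at ≥ ε, solved in units scaled by 1e5 so small supporting
fluxes register above the support threshold — flipping the orientation
(negated stoichiometric column, mirrored bounds) of reversible core
reactions that resist coverage. Core reactions blocked in the consistent
input are dropped from the core with a logged count; a protected
reaction that is blocked is an error. On small toys the output is
verified against exhaustive enumeration of minimum-cardinality
flux-consistent supersets.

## Diel multi-tissue assembly

Tissue models are namespaced (`tissue__reaction`) and joined through two
common pools: pool1 (leaf–stem) and pool2 (stem–berry), with reversible
pool-transfer reactions per exchanged metabolite (default set: sucrose,
the model's amino acids, nitrate, sulfate, phosphate, pyruvate). Because
no root tissue is modeled, mineral exchanges survive only in the stem;
water/O2/CO2 (and heat/secondary-product) exchanges stay in every
tissue; sucrose exchanges are removed so sugar must travel
leaf → pool1 → stem → pool2 → berry; the photon exchange is kept in the
leaf only.

Dielization duplicates every reaction and metabolite into light and
dark phases (`tissue__phase__reaction`) and adds one storage reaction
per tissue and storage metabolite, converting the light species 1:1
into the dark species. Sugars, organic acids, nitrate and starch are
reversible (capacity ±1000); amino acids are irreversible light→dark.
Positive storage flux therefore means "stored in light, used in dark";
listed storage metabolites absent from a tissue are skipped with a log
entry. The structural audit asserts that only storage reactions span
phases and only pool transfers span tissues, and that
`|R_diel| = 2·|R_merged| + |storage|`.

Diel constraints: photon uptake only through the leaf in the light
phase, minerals through the stem in both phases, water/O2/CO2 open
everywhere, and the nitrate 3:2 light:dark equality row. The diel
simulation fixes photon uptake (default 300), applies the Rubisco 3:1
row per phase in the leaf (the only photosynthetic tissue), maximizes
total biomass and applies pFBA. Total biomass defaults to the
unweighted sum over tissue × phase biomass fluxes; optional tissue
weights and a light:dark biomass-ratio row are supported, since no
single combination rule is canonical.

Nutrient scans re-solve the model with one exchange constrained per
level and compare FVA ranges at ≥ 80% of each optimum against the
unconstrained baseline, with pathway-level aggregation of span changes.
The default mode *caps* the uptake magnitude; a *fix* mode pins the
flux exactly, which in a minimal network without an overflow sink for
the nutrient (the toy has none for sulfur) is infeasible at high
levels — that infeasibility is reported, not raised.

## Differential flux analysis

Flux distributions are drawn with the artificial-centering hit-and-run
sampler (cobra's implementation; warm-up from per-reaction FVA optima),
default 10000 samples with thinning 100, seeded. Two implementation
details matter numerically: reactions with nonzero fixed bounds (the
maintenance flux) are widened by ±1e-6 in a sampling copy, because an
inhomogeneous equality system disables the sampler's drift
reprojection; and the chain is reprojected every 500 iterations, with
any remaining drifted draws repaired by alternating projection onto
`S v = 0` and clipping into the bounds. Samples are validated against
the 1e-6 tolerance; same seed, same matrix.

Shared reactions get a two-sample Kolmogorov–Smirnov test (asymptotic
p-values; with 10⁴ samples the exact distribution is unnecessary),
Benjamini–Hochberg adjusted across reactions; significance additionally
requires |FC| ≥ 0.82, where

    FC = (m̄₁ − m̄₂) / |m̄₁ + m̄₂|

on the sample means (0.82 corresponds to a 10-fold change; FC is 0 for
two zero means and a signed sentinel 1e6 when the denominator vanishes
but the means differ). Requiring both conditions is what keeps
self-comparisons of autocorrelated chains quiet — the KS test alone
over-rejects, a caveat inherited from the procedure rather than
corrected. Reactions absent in one model are assigned mean 0 there and
tested by a seeded percentile bootstrap (1000 resamples) of the present
model's mean: differential when 0 falls outside the 95% interval.
Pathway over-representation of altered reactions uses the upper-tail
hypergeometric test (population = compared reactions, draws = pathway),
BH-adjusted across pathways.

## Flux-capacity machine learning

Per biological sample, a context model is extracted from that sample's
expression alone, made irreversible by reversibility splitting, and
FVA at ≥ 80% of the model's own biomass optimum gives the flux capacity
`FCa(r) = max − min ≥ 0` per reaction (forward and reverse copies are
separate features). Reactions absent from a sample's model have
capacity 0; the dataset is the union-reaction samples × reactions
matrix with developmental stage (green/mature) as the label.

Evaluation runs repeated stratified cross-validation (10 folds × 10
repeats). Inside each fold, fitted on the training split only: a
zero-variance filter, ANOVA-F K-best selection (K = min(500,
remaining)), and standardization. Five classifier families with fixed
seeds: logistic regression (max_iter 2000), k-nearest neighbors
(k = 5), decision tree, RBF support-vector machine, random forest
(100 trees). Metrics use "mature" as the positive class:
recall = TP/(TP+FN), precision = TP/(TP+FP), balanced accuracy =
(recall + TN/(TN+FP))/2, F1 = TP/(TP + (FP+FN)/2); zero denominators
yield 0 with a flag. Metrics are averaged over all 100 fold × repeat
evaluations.

Attribution uses a model-agnostic permutation-sampling Shapley
estimator (default 8 permutations, seeded): for each random feature
order, features switch one at a time from the background (training-
split medians in the scaled selected space) to the test sample's
values, and the marginal change in positive-class score is credited to
the switched feature. Averaging over permutations preserves local
additivity exactly (Σφ = f(x) − f(background)). Per-sample values are
averaged over every fold in which the sample was tested; the global
ranking orders features by mean |φ|. Features never selected in any
fold get attribution 0 and are listed. The same estimator applies to
every family, so rankings are comparable across classifiers.

## The synthetic toy plant

The generator builds a ~70-reaction network over cytosol, chloroplast,
mitochondrion, vacuole and extracellular compartments, with eleven
pathway modules (light reactions, Calvin, starch, sucrose/cell-wall,
glycolysis with a fermentative overflow, TCA/respiration, amino acids,
nitrate and sulfate assimilation, an MEP-terpenoid branch, an
anthocyanin-like branch). Its chemistry is artificial but elementally
exact over C,H,O,N,S,P: every enzymatic and transport reaction balances
(tests audit this through an independent checker). Photons carry a
bookkeeping pseudo-element Z that leaves as a dissipated "heat"
metabolite, so even light-driven reactions balance. All charges are 0.

Design choices that define the study conditions:

* Per-tissue biomass pseudo-reactions with positive, sum-normalized
  substrate coefficients: stem enriched in cell-wall precursor, green
  berry in malate/citrate, mature berry in sugars plus a vacuolar
  anthocyanin-like component. Each biomass consumes 53.26 mmol·gDW⁻¹
  ATP (growth-associated maintenance); a separate ATP hydrolysis
  reaction carries a mandatory 2 mmol·gDW⁻¹·h⁻¹ (non-growth
  maintenance). Because that flux is mandatory, "no growth without
  photons and carbon" checks relax its lower bound to 0 first —
  otherwise the model is infeasible rather than non-growing.
* Terpenoid export is capped at 10 mmol·gDW⁻¹·h⁻¹ (secondary
  metabolism is low-flux), which makes the MEP branch's flux capacity a
  crisp 0-versus-cap contrast between classes.
* A fermentation route (pyruvate → acetaldehyde → ethanol, exported)
  gives pyruvate and NADPH disposal unbounded slack. Without it, the
  pyruvate-producing glycolytic step is stoichiometrically pinned and
  becomes a perfect structural proxy of the planted branch, which
  defeats any attempt to attribute the class signal to the planted
  pathway itself.
* Every enzymatic and transport reaction carries a synthetic GPR
  (cycling one-gene, two-gene OR, two-gene AND patterns); exchanges and
  pseudo-reactions are gene-free so that activity calling cannot mark
  them core.

Expression simulation draws per-gene baseline log2-TPM ~ Normal(5, 2),
adds planted per-module shifts per (tissue, stage) group, adds
replicate noise ~ Normal(0, 0.25), clips at 0 and exports
TPM = 2^log2 − 1 (so the preprocessing log2(x+1) round-trips exactly).
The default design: leaf and stem (3 biological samples × 2 replicates
each) and an 8-time-point berry course (4 biological × 2 replicates per
time point; time points ≤ 4 are green, > 4 mature). Default planted
effects: photosynthesis modules +3 in leaf; the MEP-terpenoid and
anthocyanin-like modules −6 in green berries and +3 in mature berries.
A `PlantedTruth` record carries the effects and the module→gene/reaction
maps, and all recovery tests read their expectations from it.

What the generator does *not* emulate: realistic grape biochemistry or
pathway coverage, count noise/library-size effects (values are exact
TPM), batch effects, correlated gene programs beyond the planted
modules, or isoform complexity. Passing recovery tests therefore show
that the statistics and learners recover a planted signal of realistic
shape through the full pipeline — not that they would perform equally
on real RNA-Seq.

## Problem sizes in the shipped tests

The test suite runs the full route at desk scale: ~70-reaction models,
38 expression columns (32 berry biological samples for the per-sample
analyses), ACHR chains of 2000 samples × thinning 20 for the planted-
difference comparison and 10⁴ × 100 for the calibration checks on
small polytopes, 10 × 10 cross-validation on the 32-sample dataset, and
8-permutation Shapley estimates. The sampler, thresholds and
cross-validation defaults remain the protocol values (10⁴/100, 25/75/50,
ε = 1e-4, α = 0.05, |FC| ≥ 0.82, photon 300, FVA fraction 0.8,
10 × 10 × 500).

## Known limitations

* KS tests on autocorrelated chain samples over-state significance;
  the FC cutoff mitigates but does not remove this (kept by design).
* FASTCORE is approximately minimal; minimality is only verified
  exhaustively on small toys.
* The total-biomass combination rule (unweighted sum) is one defensible
  choice among several; tissue weights and a phase-ratio row are
  exposed but unvalidated.
* The sampler's bound-jitter for nonzero fixed fluxes perturbs those
  fluxes by up to 1e-6, which is visible if a fixed flux is compared at
  tighter tolerance.
* Shapley values split credit among correlated features; rankings are
  stable for crisp planted contrasts but should be read at pathway
  level when features are strongly coupled.
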