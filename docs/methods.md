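# Methods

## The simulation model

A structured host population is two demes S1, S2. Per-lineage rates are birth
λᵢ, death μᵢ and emigration αᵢⱼ (all per unit model time; per year in the
HIV defaults). The process starts from one lineage in a configurable deme
(default deme 1) and proceeds event by event:

1. the deme hosting the next event is drawn with probability
   T_Sᵢ / (T_Sᵢ + T_Sⱼ), T_Sᵢ = λᵢ + μᵢ + αᵢⱼ, restricted to demes with at
   least one extant lineage (selecting an empty deme would deadlock, so
   empty demes get weight zero). A `deme_weighting="population"` option
   uses the classical Gillespie weights Nᵢ·T_Sᵢ instead; the sub-total-rate
   rule is the default because it is the procedure the simulated datasets
   are defined by.
2. the waiting time is exponential with rate Nᵢ(t)·T_Sᵢ for the selected
   deme and advances the global clock; branch lengths are differences of
   event times (O(1) bookkeeping per event).
3. the affected lineage is uniform among the deme's extant lineages
   (lineages are exchangeable), and the event type is birth, migration or
   death by the thresholds λᵢ/T_Sᵢ and (λᵢ+αᵢⱼ)/T_Sᵢ.

Births create a bifurcation; migrations create a unifurcating colour-change
node whose single child carries the other deme label; deaths terminate the
lineage. After termination, dead lineages are pruned: pruning-induced
unifurcations are collapsed (branch lengths summed) while migration
unifurcations are retained — they are part of the observable tree shape in
this model. If the whole population dies before the target size, the
attempt restarts from scratch (up to 100 retries) so only completed trees
are reported.

**Termination.** The run stops when the total number of extant lineages
reaches the configured target (the sum of the per-deme targets), so every
tree has exactly the configured tip count. A `termination="joint"` option
stops instead at the first moment both demes simultaneously meet their
per-deme quotas; with the default rates deme 2 grows faster
(λ₂−μ₂−α₂₁ ≈ 3.78 vs ≈ 2.75 per year), so under the joint rule it
overshoots its quota by the time deme 1 catches up — which is why the total
rule is the default. The rule used is recorded in each tree's metadata.

**Reproducibility.** Each tree in a dataset gets its own
`numpy.random.Generator` seeded as (dataset seed + replicate index) mod 2³¹,
so datasets are reproducible and replicates independent of generation order.

## R0 and parameter derivation

The deterministic counterpart is the linear ODE system with disease-free
equilibrium (0,0); R0 is the dominant eigenvalue of F·V⁻¹ with
F = diag(λ₁, λ₂) and V = [[α₁₂+μ₁, −α₂₁], [−α₁₂, α₂₁+μ₂]]. The closed form

R0 = (α₂₁λ₁ + α₁₂λ₂ + λ₂μ₁ + λ₁μ₂ + √Δ) / (2(α₂₁μ₁ + (α₁₂+μ₁)μ₂))

is tested against the numerically inverted F·V⁻¹ eigenvalue to 10
significant digits on 1000 random rate draws; Δ equals tr² − 4·det of the
next-generation matrix times the squared denominator and is nonnegative for
nonnegative rates (real eigenvalues), asserted as a property test.

Simulation birth rates are derived from literature R0 targets through the
**per-deme convention** λᵢ = R0ᵢ·(2αᵢⱼ + μᵢ) (reducing to λ = R0·μ without
migration). Note this convention is *not* the dominant eigenvalue of F·V⁻¹
for the coupled system: with identical demes and symmetric migration the
eigenvalue is λ/μ, not λ/(2α+μ). The convention is nevertheless the defining
parameterisation of the simulated datasets (it is what maps R0 = 4.99 and
9.09 to λ = 3.0639 and 4.0178), so both quantities are exposed —
`r0_scaled_structured` / `birth_rate_from_r0` for the convention, and
`r0_general` / `r0_numeric` for the true coupled-system R0 — and they are
deliberately not asserted equal.

Default rates emulate HIV in a two-risk-group host population: μ = 0.014/yr
(tripled in the high-risk deme), α = 0.3 and 0.2/yr, R0 = 4.99 (low risk /
non-structured) and 9.09 (high risk). R0 ≤ 1 in both demes triggers a
warning, not an error: subcritical simulation is meaningful, it just rarely
completes.

## Tree-shape statistics and migration-node conventions

The eleven per-tree quantities are the eight raw statistics plus normalised
cherries (÷ n/2), Sackin (÷ 0.5n(n+1) − 1, the caterpillar maximum) and
Colless (÷ (n−1)(n−2)/2). All are invariant to branch lengths and child
order (property-tested). Migration unifurcations require a convention, fixed
as follows and verified in full against the five-tip worked example:

* **depth-type** statistics (Sackin, max depth, max width, cophenetic LCA
  depth) count migration nodes and their edges;
* **balance-type** statistics (cherries, Colless) treat migration nodes as
  transparent pass-throughs;
* the **ladder** counts internal nodes with exactly one leaf child, so a
  migration node whose child is internal never extends a ladder.

This is the only assignment consistent with every worked-example value
(cherries 2, Sackin 14, Colless 2, cophenetic 6, ladder 0.2, depth 3,
width 4) on a five-tip tree with one migration node. The total cophenetic
index is computed in O(n) via Σ_{v ≠ root} C(k_v, 2) over subtree leaf
counts k_v, with an explicit pairwise-LCA oracle in the tests.

## Two-sample tests

The Kolmogorov-Smirnov test is scipy's, in asymptotic two-sided mode.
Cucconi and Podgor-Gastwirth follow the standard comparative-review
formulations: Cucconi's C combines the standardised sums of squared midranks
(U) and squared contrary ranks (V) with their correlation ρ; under the null
C is asymptotically exponential(1), so p = exp(−C). The Podgor-Gastwirth
statistic S is the joint F statistic of the OLS regression of the group
indicator on (midrank, midrank²), referred to F(2, N−3). Both statistics are
exactly symmetric in the two samples and invariant under strictly monotone
transformations. The permutation p-value (B = 9999 by default, seeded) is
the default for the individual test functions, with the asymptotic tail as
an option; the combined report defaults to asymptotic p-values (only an
asymptotic tail can resolve values like 10⁻²⁰) and records which mode was
used. Ties are midranked — essential because the tree statistics are
integer-valued. Type-I error of both tests at α = 0.05 is calibrated within
±0.02 over 1000 null simulations; an exact enumeration oracle over all
relabellings validates the permutation p on small samples.

## Classification

Features are the eight statistics (normalised cherries/Sackin/Colless, raw
cophenetic, ladder, max width, max depth, width-depth ratio), standardised
within training data only (SVMs and KNN are scale-sensitive). Grids:
k ∈ {3,5,7,9,11}; polynomial degree ∈ {2,3,4} × γ ∈ {0.01,0.1,1} (C = 1 for
all SVMs); radial γ on a five-point grid around the median heuristic; decision
tree cost-complexity α on a log grid. Hyperparameters are chosen once by
grid search with cross-validated accuracy, then the tuned pipeline is scored
under stratified 10-fold cross-validation; reported metrics are per-fold
means (sensitivity, specificity, accuracy, AUC) with "structured" as the
positive class, and the confusion matrix pools held-out predictions. AUC is
trapezoidal integration of the ROC curve and equals the pairwise-concordance
formulation (oracle-tested). SVM scores are signed decision values; KNN and
decision-tree scores are class probabilities.

## Datasets and sensitivity analysis

The baseline dataset is 500 non-structured trees (350 tips) and 500
structured trees (350/200 deme quotas) at the default rates. The tree count
per class is configurable: the per-sub-population table that motivates the
structured parameters can be read as either 250 or 500 structured trees; 500
is the default because a ~30 % test split of ~1000 trees matches the
reported 307-case evaluation fold. Sensitivity modes re-simulate 250 + 250
trees with Latin-hypercube draws (scipy's stratified sampler): tree sizes
from (300,400) / (250,300) per deme, and/or per-deme R0 from (0.45, 6.34)
and (4.18, 36.75). In the varied-parameters modes only the structured demes
vary: the deme-1 interval dips below the R0 = 1 persistence threshold, which
a structured tree tolerates (deme 2 remains strongly supercritical and
re-seeds deme 1 by migration) but under which a non-structured tree of 350
tips could never complete, so non-structured rates stay at baseline. A
"dataset 2" variant draws tip counts uniformly from (300,400) / (150,250).

## What the generator does and does not emulate

Simulated trees are complete transmission trees: every extant lineage is
sampled exactly once at a single time point, there is no serial or
incomplete sampling, no more than two demes, and no sequence evolution or
phylogenetic reconstruction error. Classifiers trained on such trees exploit
both shape differences *and* the systematic tip-count difference between the
classes (350 vs 550 in the baseline); passing tests therefore demonstrate
that the pipeline recovers the structure signal under its own generative
model, not that real reconstructed trees (with sampling biases and
inference noise) would be classified with the same accuracy.

## Problem sizes and numerical choices

The test suite exercises the simulation-based checks at 150 + 150 trees at
the full 350/550 tip counts — the separation and classification behaviour is
stable at that scale and the suite stays fast; the acceptance script runs
the full 500 + 500 benchmark. Degenerate inputs are errors, not silent
results: empty demes for waiting times, extinct populations, all-tied
samples for the rank tests, single-class inputs for classifiers,
single-tip trees for the width-depth ratio. Permutation p-values use the
add-one rule (b+1)/(B+1); Cucconi/PG statistic comparisons in permutation
counts use a 10⁻¹² tolerance to absorb floating-point ties. Newick output
writes deme labels and migration flags as bracketed node comments and
serialises unifurcations explicitly; parsing (via DendroPy) restores them,
and an unflagged unifurcation whose child changes deme is recognised as a
migration node.

## Known limitations

The ladder-chain and cherry conventions at migration nodes are fixed by a
single worked example; other conventions are conceivable and would change
those two statistics on structured trees. The joint-quota termination rule
lets the faster deme overshoot its quota (documented above). The
Podgor-Gastwirth asymptotic reference F(2, N−3) is a large-sample
approximation; for small samples use the permutation mode.
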