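# Methods

This note documents the models, parameter choices and numerical
conventions behind `eigennet`, and what the synthetic benchmarks do and do
not demonstrate.

## Preprocessing

Expression values are assumed to be on a log scale; raw abundance (e.g.
RPKM) can be transformed with `ln(v + pseudocount)` (default pseudocount
1). Gene rows containing missing values are dropped at ingestion —
correlation and PCA downstream require complete rows, and imputation is
out of scope. Gene identifiers are matched by exact, case-sensitive string
equality.

The differential-expression filter ranks genes by the raw Welch p-value
(smaller first), breaking ties by larger |t| and then lexicographic gene
id, and keeps `ceil(fraction · n)` genes (default fraction 1/3). Raw
rather than adjusted p is used for ranking: Bonferroni scaling is
monotone, so the order would be identical, but raw values avoid mass ties
at 1.0.

## Coexpression network and modules

The network is unsigned: `a_ij = |cor_ij|^β` with Pearson correlation
across samples. The soft power β is the smallest candidate (default 1–12)
whose connectivity distribution passes the scale-free criterion at
`R² ≥ 0.8`. Two numerical details matter here:

* The fit index is **signed**: the log–log regression of bin frequency on
  mean connectivity must have a *negative* slope to count. An unsigned R²
  can pass on a rising distribution (frequency increasing with
  connectivity), which is the opposite of scale-free topology; we observed
  exactly this failure on strongly modular data at β = 1.
* When no candidate passes — the norm for data dominated by a few large
  modules, whose connectivity distribution is bimodal rather than
  scale-free — the operation's default falls back to the best-scoring
  candidate, but the pipeline pins the fallback to β = 6, the published
  default for unsigned networks in the coexpression-analysis literature.
  Maximizing a noisy R² over candidates is unstable (adjacent seeds chose
  β ∈ {1, 4, 12}, with module recovery collapsing at the extremes); a
  pinned fallback is deterministic and well-behaved.

Dissimilarity is `1 − TOM` with
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`; isolated
pairs (zero denominator) get `TOM = 0`. Modules are flat clusters of an
average-linkage dendrogram cut at a static height (default 0.95); clusters
smaller than `min_module_size` (default 20) are reassigned to module 0
(unassigned), and surviving modules are renumbered 1..M by decreasing
size, ties broken by smallest member gene id. The static cut replaces the
dynamic branch-cutting of the original framework, which is out of scope.
The 0.95 default sits in the empirically wide gap between within-module
merge heights (~0.5–0.8 at β = 6) and between-module heights (~0.96–1.0)
on the synthetic benchmark; note that two condition-associated modules are
*correlated through the phenotype* (their latent factors share the
condition shift), so a cut too close to 1 merges precisely the modules of
interest.

## Eigengenes

Class balancing by oversampling repeats every sample of condition *c*
`r_c = max(1, round(target / n_c))` times (round half up, for platform
independence). `target = "auto"` uses 9 × the larger class size, which
reproduces the canonical 202/164 → 9×/11× worked example. Balancing
affects only the weight fit; eigengene values are always reported for the
original samples, once each.

Per module, member genes are z-scored (mean 0, sd 1, `ddof = 1`) across
the balanced samples and the weight vector is the first right singular
vector of the samples × genes matrix — the unit-norm direction maximizing
explained variance. The sign is fixed so the eigengene correlates
non-negatively with the members' mean scaled profile (falling back to
making the largest-|weight| entry positive in the degenerate zero-
correlation case), which makes recomputation bit-reproducible.

**Projection** evaluates a trained module in any dataset: genes common to
the model and the dataset are z-scored *within that dataset*, the
surviving weight sub-vector is rescaled to unit norm, and the eigengene is
the weighted sum. Per-dataset scaling is the cross-platform mechanism:
only the shape of each gene's variation matters, not its platform-specific
scale.

**Normalization of reported values.** Projected eigengene columns are
scaled to unit sample variance. The raw weighted sum of correlated
z-scores has standard deviation ≈ `sqrt(n_genes · mean cor)`, so its scale
depends on how many genes back the module. Two consumers break without
normalization: frozen decision-tree thresholds (gene removal during
compaction would shrink all values toward zero and sweep samples across
the threshold — we measured ~9-pp accuracy collapses) and cross-dataset
comparison when gene coverage differs. Unit-variance reporting makes
thresholds scale-stable; it is also consistent with near-zero thresholds
being meaningful for such "normalized eigengene" features.

## Bayesian network over eigengenes

Eigengenes are discretized into terciles by empirical quantiles (the
smallest level count able to express non-monotone dependence); a binary
`Disease` column (1 = the designated positive label, default the
lexicographically larger one) is appended. Structure is learned by greedy
hill climbing — add/delete/reverse of one arc — maximizing the
decomposable multinomial BIC
`Σ N_ijk ln(N_ijk/N_ij) − (log n / 2) Σ (r_i − 1) q_i`. Arcs into
`Disease` are blacklisted, so modules can only be its children, making
"children of Disease" a well-defined feature-selection rule. The seed
shuffles move-evaluation order, fixing tie-breaks without a node-order
bias.

Hill climbing is exact on pairwise-detectable structure but blind to pure
parity dependence: in an XOR collider every pair of variables is
marginally independent, so no single-arc move improves on the empty graph.
Optional seeded restarts from random DAGs (default 0) recover such
structures; with a handful of restarts the search attains the exhaustive
25-DAG optimum on three-node benchmarks. A related caveat: the XOR joint
is score-symmetric under all three collider orientations (each variable is
the XOR of the other two), so no score-based method can orient it; the
identifiability benchmarks in the test suite therefore use a noisy-OR
collider, whose v-structure is the unique optimum of its equivalence
class.

The consensus network learns on `n_boot` bootstrap resamples (default
100, seeds `seed+1 … seed+n_boot`), defines direction-specific arc
strength as the fraction of resamples containing the arc, keeps arcs with
strength ≥ 0.5, and breaks any residual cycle by dropping the cycle's
weakest arc. `disease_children` orders children by descending strength,
then ascending id.

## Decision tree and compaction

The tree performs recursive binary splitting on single eigengene features,
choosing the (feature, threshold) pair with the largest information gain
ratio among midpoints of consecutive distinct values; children smaller
than `ceil(0.10 · n_train)` samples are never created, recursion stops on
pure nodes or non-positive gain, and leaf labels are the majority class
(ties to the smaller label code). There is no pruning beyond the leaf
floor.

Compaction iterates: among all genes backing the tree's feature modules
(modules reduced to one gene are irreducible), remove the one with
smallest |weight| (ties by gene id), renormalize the remaining weight
sub-vector, re-project eigengenes, and re-evaluate per-class training
accuracy with the tree structure and thresholds bit-identical. The stop
rule is parameterized: removal halts when the next step would push any
class more than `max_drop` (default 0.05) below its initial accuracy, or
at `min_genes`. Setting `max_drop = 1` with a gene-count target instead
measures the accuracy cost of compacting to a fixed fraction of genes.

## Synthetic data

Each module *m* has one latent factor per sample,
`f_ms ~ Normal(±effect_m/2, 1)` with the sign set by the sample's
condition; gene *g* in module *m* is `λ_g f_ms + ε`,
`λ_g ~ Uniform(0.6, 0.95)`, `ε ~ Normal(0, 0.5²)`. Background genes (20%
of the total) are unit-variance noise. This is the minimal generative
model under which the first principal component is the *correct* module
summary, so parameter recovery is well defined. Defaults: five modules of
sizes (100, 100, 100, 90, 90) plus 120 background genes (600 genes), 120
samples per condition (240 total), effect sizes (3.0, 2.0, 0, 0, 0). The
two nonzero effects give eigengene Welch statistics of |t| ≈ 15–23 at
these sample sizes (adjusted p ~ 10⁻³⁰…10⁻⁵⁰), i.e. separation of the
same order as strong disease-module signatures in real two-entity
cohorts, and an end-to-end two-feature tree accuracy in the low-to-mid
90% range — deliberately not a trivially separable benchmark.

What passing the synthetic suite shows: the pipeline recovers planted
module structure (ARI ≥ 0.8), eigengenes track the latent factors
(|cor| > 0.95), frozen-weight projection agrees with independent refits
(|cor| ≥ 0.9), and compaction exploits within-module redundancy. What it
does not show: robustness to probe-level artifacts, batch effects,
count-level (negative binomial) noise, nested or overlapping modules, or
module-size distributions of real transcriptomes — none of which the
generator emulates.

## Problem sizes and runtime choices

The default benchmark (600 genes × 240 samples, 100 bootstrap resamples
over ≤ 6 network nodes, 10,000 null simulations for test calibration) was
chosen so a complete from-scratch reproduction, including the test suite,
runs in well under a minute on one CPU; all matrices fit comfortably in
memory as dense arrays. Blockwise computation for very large gene sets
(> 20k) is a non-goal.

## Known limitations

* The static dendrogram cut needs a dataset-appropriate height; strongly
  correlated modules can merge (the run log reports module sizes, and the
  cut is configurable).
* Consensus arc strengths are meaningful only for identifiable
  equivalence classes; compelled arcs (immoralities) concentrate, while
  reversible arcs dilute across orientations.
* The Bayesian network is used for feature selection only; conditional
  probability tables are not fitted and no inference queries are
  supported.
* Binary phenotypes only; multi-class trees and survival endpoints are
  out of scope.
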