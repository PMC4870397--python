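# Methods

This note records the statistical model behind `gsabench`, the conventions
the implementation fixes where the underlying constructions leave freedom,
and the limits of what the simulation study can show.

## Count model and parameter pool

Counts are simulated as Y_gj ~ NB(mean = μ_g, var = μ_g(1 + μ_g φ_g)),
independently across genes and samples; φ_g = 0 degenerates to Poisson.
Per-gene parameter triplets (μ, φ, length) are drawn uniformly **with
replacement** from a pool, mimicking how benchmark studies resample
empirical (mean, dispersion, length) estimates from a reference dataset.

The synthetic pool generator produces:

* `mu` — log-normal, log μ ~ N(ln 100, 1.5²). Spans ~0.5 to tens of
  thousands of reads, covering low- to high-expression genes.
* `phi` — a decreasing mean–dispersion trend φ = b + a/μ with defaults
  (a, b) = (3, 0.05), jittered multiplicatively by log-normal noise with
  σ = 0.3 on the log scale. This reproduces the empirical shape seen in
  bulk RNA-seq dispersion estimates: small, noisy dispersions for highly
  expressed genes, large dispersions at low counts.
* `length` — log-uniform on [200, 20 000] bp.

All defaults are configurable; a pool can also be loaded from a TSV with
columns `mu`, `phi`, `length`. Because every test here is calibrated by
permutation, Type I error conclusions are insensitive to the exact pool;
power levels (but not their orderings or trends) do depend on it.

Each replicate dataset draws fresh triplets from the pool; the draw is part
of the per-replicate seed stream, so experiments are reproducible from a
single master seed.

## Simulation designs

A dataset has S non-overlapping sets of p genes (genes `g000001`…, sets
partitioning them in index order) and N samples split N/2 / N/2 into
phenotypes 1 and 2. Under the null, each gene's triplet generates counts
identically for all N samples. Under the alternative, the first
round(β·S) sets are flagged DE; within each, the first g = round(γ·p)
genes are DE with fold change FC ≥ 1:

* `balanced` — the first ⌈g/2⌉ DE genes have mean FC·μ in phenotype 2,
  the remaining ⌊g/2⌋ have mean FC·μ in phenotype 1;
* `one_sided` — all g DE genes are up in phenotype 2 (the convention is
  arbitrary but fixed).

Flags follow the design even at FC = 1, where "DE" sets carry no signal;
this makes the boundary check power(FC = 1) ≈ α directly computable.
Rounding makes arbitrary (β, γ, p, S) grids safe; β·S rounding to zero
with β > 0 is an explicit error rather than a silent null design.

## Normalizations

* RPKM = 10⁹ · count / (library_size · gene_length) feeds the multivariate
  tests, which compare samples as points in R^p.
* log-CPM = log₂((count + 0.5)/(library_size + 1) · 10⁶) feeds SAM-GS, the
  gene-level tests and the competitive ranking. The 0.5/1 offsets follow
  the limma/voom convention — the one place a convention is imported from
  outside this package; voom's precision weights are *not* computed, since
  no linear-model pipeline here consumes them.

Library sizes are always recomputed as column sums, also after
subsampling.

## Test statistics and fixed conventions

**N-statistic.** Implemented exactly as the energy-type form
(n₁n₂/(n₁+n₂))·√[B − W₁ − W₂] with B the mean between-group Euclidean
distance and W₁, W₂ half the mean within-group distances. The bracket is
clipped at zero before the square root to absorb round-off. The classical
energy statistic differs from this form by constant factors; permutation
inference is invariant to monotone rescaling, so conclusions agree either
way.

**SAM-GS.** T = Σ((X̄ᵢ−Ȳᵢ)/(sᵢ+s₀))² with sᵢ the pooled SD
(n₁+n₂−2 denominator). s₀ policies: `zero`, `fixed:<x>`, and the default
`median_sd` — the median of gene-wise pooled SDs over the whole dataset,
computed once from the observed labeling and held fixed across
permutations (the original SAM percentile search is out of scope; the
policy is pluggable). A zero pooled SD with s₀ = 0 is an error.

**MST-KS.** The pooled N samples form a Euclidean graph; its minimum
spanning tree is built with Prim's algorithm (ties by lowest sample index,
so duplicate points are handled deterministically). Samples are ranked by
a depth-first traversal rooted at a node of maximum hop-count eccentricity
(ties by lowest index), visiting children in increasing edge-weight order
(ties by lowest index). The statistic is max_r |#{group 1 among first
r}/n₁ − #{group 2}/n₂|. The traversal conventions are fixed and
documented; any fixed convention yields a valid permutation test.

**Gene-level tests.** Per-gene two-sided P-values on log-CPM from Welch's
t (default) or a moderated t that shrinks pooled variances toward the
across-gene mean with fixed prior weight d₀ = 4 — a deliberately simple
fixed-shrinkage stand-in for empirical-Bayes machinery; the subject-
sampling null makes the set-level test calibrated for any plug-in gene
engine, which is exactly the property being benchmarked. Constant genes
get P = 1. Combiners: FM (−2Σ ln pᵢ, default), SM (ΣΦ⁻¹(1−pᵢ)/√p), GM
(ΣQ_gamma(1−pᵢ; shape), default shape 0.5; shape 1 reduces GM to FM/2).
P-values equal to 1 would map to −∞ under the SM/GM transforms and are
backed off to 1 − 10⁻¹²; zeros are clipped to the machine minimum with a
warning (permutation P-values cannot be 0 by construction). A χ²
asymptotic P-value for FM is available for comparison but never used in
the evaluation harness — it assumes independent genes, which correlated
expression violates.

**Competitive test.** For one sample, genes are ranked by decreasing
expression (ties by gene index) and the set score is Σ_r [ECDF_in(r) −
ECDF_out(r)], with in-set genes weighted by |expression|^τ (default
τ = 0.25; τ = 0 is purely rank-based and is used by the invariance tests)
and the out-set ECDF unweighted. Summing the ECDF difference over ranks
collapses to a closed form in the rank positions, which is how the
vectorised score matrix is computed; a literal walking implementation is
kept as the reference. Scores are compared between phenotypes with an
absolute pooled-variance t statistic under label permutation; constant
score rows give P = 1.

## Permutation engine

All tests share one subject-sampling engine. Group sizes are preserved;
when the number of distinct label splits is at most `exhaustive_threshold`
(default 2000) the splits are enumerated exhaustively — for balanced
groups, complementary splits are collapsed (all statistics here are
invariant to swapping the groups), e.g. 126 splits at N = 10 — otherwise
`n_perm` (default 1000) uniform random splits are drawn. P-values are
p = (1 + #{null ≥ observed})/(1 + B) in random mode and the enumeration
fraction in exhaustive mode; ties are counted with a small relative
tolerance so float round-off cannot drop exact ties. Detection uses
P < α with α = 0.05 and no multiple-testing correction, matching the
proportion-of-sets protocols. Null splits are shared across the sets of
one dataset, which leaves each set's marginal test exactly valid and makes
whole-collection runs vectorisable.

### Known limitation: tie-induced conservatism of MST-KS

The KS statistic takes values on the grid of multiples of 2/N, so its
permutation null has large point masses. Counting ties as
at-least-as-extreme (required for exactness) puts the attained level
below α whenever a point mass straddles the α-quantile: measured levels
are ≈ 0.009 at N = 10, ≈ 0.027 at N = 20, ≈ 0.035 at N = 40. This is a
property of any exact test of a heavily tied statistic, removable only by
randomized tie-breaking or mid-p corrections, which would break the
p-value convention above. The test is valid (never anti-conservative);
reported inflation of MST-KS tests at small N elsewhere in the literature
is consistent with an asymptotic rather than permutation null.

## Evaluation protocols

* **Type I error** — proportion of S = 1000 null sets detected at
  α = 0.05, averaged over 10 replicate datasets (10⁴ set-tests per cell;
  Monte-Carlo SE ≈ 0.0022).
* **Power** — detected fraction among truth-DE sets, with the truth-null
  detection fraction reported alongside, so both are recoverable.
  Competitive and gene-level methods see the whole S·p-gene dataset;
  self-contained methods only ever use each set's own genes.
* **Robustness** — a surrogate gold standard GS_TP/GS_TN is fixed by the
  full-data run; B balanced subsets per subset size n (n/2 per phenotype,
  without replacement) give per-set detection rates m(i,n) and e(i,n) and
  their means TPR(n), FPR(n). The CCDS curve is built from s_k (sets
  detected in exactly k subsets) and Q = Σ k·s_k (total detection
  events — the only reading under which CCDS(B) = 1): CCDS(b) =
  Σ_{k≤b} k·s_k / Q. A curve that saturates at low b flags a method whose
  detections wander with sample composition.
* **Detection bias** — mean set size, mean fraction of per-gene-DE genes
  (Welch on log-CPM at α = 0.05) and mean gene length across each
  method's detected sets, with two-sided Wilcoxon rank-sum contrasts
  between methods.

Problem sizes in the shipped experiments (Type I at S = 1000 × 10
replicates; power and balance at S = 200 × 3 replicates; robustness at
B = 20, sizes {28, 18} on an N = 40, FC = 1.5 reference dataset) were
chosen so the whole benchmark reruns in minutes on one CPU while keeping
Monte-Carlo noise well inside the decision margins being tested.

## What the simulations do and do not show

The generator reproduces the features the tests are sensitive to: NB
mean–variance structure, realistic dynamic range, gene-length variation,
and planted DE with controlled balance. It does **not** simulate
inter-gene correlation within sets (except in a dedicated latent-factor
calibration test), batch effects, sample-specific composition biases,
isoform structure, or outlying samples. Consequently, passing Type I and
power checks here demonstrates correctness of the tests under the stated
model, not performance on any particular real dataset; the robustness
machinery runs on simulated reference data and demonstrates the
*machinery* and the qualitative self-contained vs competitive contrast,
not field-data effect sizes. One deliberate side effect is visible in the
`one_sided` design: many DE genes up in one phenotype shift that
phenotype's library sizes, so normalized null genes drift the other way
and the truth-null detection rate rises — a real compositional effect of
library-size normalization, reported separately from power rather than
hidden.
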