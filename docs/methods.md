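# Methods

## The statistical picture

A metacell is a group of single cells aggregated into one expression
profile, on the premise that its members share a biological state.  We
formalize the state of a cell as its relative feature-abundance vector
λ = (λ₁, …, λ_p), Σλ_j = 1: a metacell is *trustworthy* when all of its
cells share the same λ, and *dubious* otherwise.  Under the standard
hierarchical view of droplet sequencing, a cell's observed counts given λ
and its library size y₊ are multinomial, Mult(y₊, λ).  Two consequences
drive everything in this package:

* **Within a trustworthy metacell, features are essentially uncorrelated.**
  The only correlation is the slight negative one forced by the sum
  constraint, −√(λ_j/(1−λ_j))·√(λ_ℓ/(1−λ_ℓ)) for features j and ℓ
  (`theoretical_within_correlation`), which is negligible once p is large.
  A metacell mixing two states instead shows genuine feature correlations:
  every feature that separates the states co-varies with every other.

* **Averaging relative abundances over a trustworthy metacell is an
  unbiased, variance-reduced estimate of λ.**  Mixing states biases the
  aggregated profile, and the bias propagates: for 50/50 two-state mixtures
  the metacell-level covariance estimate between features j and ℓ shifts by
  (λ¹_j λ²_ℓ + λ²_j λ¹_ℓ − λ¹_j λ¹_ℓ − λ²_j λ²_ℓ) / (2(M−1))
  (`theoretical_mixture_bias`).  Both closed forms are verified against
  Monte-Carlo simulation in the test suite.

## Divergence score and its permutation null

For each metacell with normalized block X (m cells × p features) we compute
the Pearson feature-correlation matrix R and summarize its deviation from
the identity as ‖R − I‖_F.  The raw deviation is meaningless on its own —
it scales with m, with the number of usable features, and with the block's
sparsity — so it is normalized by the same deviation after a within-feature
permutation (each column shuffled independently), which preserves all
marginals but destroys dependence:

    mcDiv = ‖R − I‖_F / ‖R̃ − I‖_F.

Thresholds come from a null score computed per metacell by the double
permutation: first a *within-cell* shuffle (each row permuted, preserving
every cell's value multiset and hence its library-size footprint), then a
within-feature shuffle of the result:

    mcDiv_null = ‖Π − I‖_F / ‖Π̃ − I‖_F.

The within-cell step is what conditions the null on technical cell-to-cell
variation: cells differ in sequencing depth, and residual depth effects in
normalized data induce correlations that have nothing to do with state
mixing.  A baseline that only permutes within features (available as
`null="within_feature"`) ignores this and grossly over-flags homogeneous
metacells whenever library sizes vary — the package quantifies this failure
mode in its acceptance tests.

### Abundance-stratified within-cell permutation

An unrestricted within-cell shuffle preserves row sums but homogenizes the
feature marginals: every permuted column becomes a mixture of all features'
values.  That discards two things the null must keep.  First, a feature's
response to depth variation is a function of its abundance — near zero for
densely observed features, strong for sparse ones — so the homogenized null
reproduces only the *average* depth response (effectively E[a]² where the
data contains E[a²] across per-feature loadings a).  Second, the sampling
noise of a correlation-matrix deviation depends on the sparsity mix of the
columns; homogenized columns concentrate the null far more tightly than the
observed statistic.  Both effects push null scores below the scores of
genuinely homogeneous metacells, and in simulation with realistic feature
heterogeneity the unrestricted null false-flags 30–80 % of purity-1
metacells — at any data regime we tested, not as a corner case.

The within-cell permutation here is therefore *stratified by abundance*:
features are ranked by their within-block mean and paired (rank bins of
two), and each cell's values are shuffled only within bins.  Each row is
still a permutation of itself (row sums exact), but each permuted column
now retains, to first order, its own marginal profile and depth loading.
Dependence between features in different bins — which is where essentially
all of a mixture's signal lives, since pairing is by abundance, not by
state — is still destroyed; dependence within a pair survives but
contributes O(p) of the O(p²) terms in the Frobenius norm.  With this null
the detector is calibrated: on semi-synthetic data ≈99 % of purity-1
metacells are retained at the 95 % threshold while 50/50 mixtures are
flagged with recall ≈1.  The bin size is exposed (`bin_size`, default 2;
`None` gives the unrestricted shuffle) for users who want the cruder null.

### Thresholding

Null-score distributions shift with metacell size, so the threshold for a
metacell of size m is the q-quantile (default q = 0.95, linear/type-7
interpolation — a convention we fix for reproducibility) of null scores
from metacells with sizes in [m − h, m + h], bandwidth h = 10.  Windows
holding fewer than 5 nulls are widened in steps of 5; if the data cannot
satisfy the minimum the global quantile is used.  A metacell is dubious iff
its mcDiv *strictly* exceeds its threshold.  Each permutation is drawn once
per metacell from a stream seeded by (global seed, metacell id), so adding
or removing metacells never perturbs the others' scores.

Degenerate inputs: metacells with fewer than 3 cells are not scored (at
m = 2 every correlation is ±1 and mcDiv ≡ 1 carries no information) and are
classified trustworthy with an `insufficient_size` flag; features constant
within a block (within a relative tolerance of 10⁻¹⁰ to absorb float
rounding) are dropped from both numerator and denominator, and blocks with
fewer than two usable features get `insufficient_features`.

## Granularity optimization

A partition produced by any metacell method at granularity γ (average cells
per metacell) is scored by

    Score = 1 − w·DubRate − (1 − w)·ZeroRate,   w ∈ (0, 1), default 0.5,

where DubRate is the fraction of *all* cells (unassigned included) lying in
dubious metacells and ZeroRate is the fraction of zeros in the M × p
aggregated count matrix over the selected features (the zero pattern of
sums equals that of means).  Small γ keeps metacells pure but sparse; large
γ merges states.  The Score-maximizing configuration is selected, ties
going to the smaller γ (fewer cells merged) and then to method name order.
HVGs are selected once per dataset, not per γ.  Partitioners plug in as
callables `(NormalizedMatrix, γ, seed) → MetacellPartition`; the built-in
baseline (PCA to ≤30 components, 15-NN connectivity graph, Ward
agglomeration to exactly ⌊n/γ⌋ clusters) exists to make the sweep
self-contained and testable, not to compete with dedicated metacell
methods.

The optional two-step refinement re-detects at a relaxed 85th-percentile
threshold, pools the cells of flagged metacells, and re-partitions that
pool at the chosen γ; pools smaller than γ become a single metacell.  One
round is performed.

## Preprocessing

Counts are log-normalized as ln(1 + y_ij/y_i₊ · 10⁴) once on the full
dataset; metacell blocks are slices of this matrix.  Feature selection
ranks features by a variance-stabilized dispersion: a quadratic fit of
log₁₀ variance on log₁₀ mean predicts each feature's expected variance,
counts are standardized by the predicted SD with values clipped at √n, and
features are ranked by the variance of the clipped standardized values
(ties broken by feature order; constant features excluded).  This follows
the shape of the widely used "vst" ranking without chasing bit-level
equality with any particular implementation; detection output is stable
across p ∈ {1500, 2000, 2500} on simulated data (Jaccard of dubious sets
≥ 0.8 in the test suite at reduced scale).

## The synthetic-data generator

`simulate_dataset` emulates the hierarchical count model directly.  Each
true metacell k (sizes integer-uniform on [20, 80], adjusted so the mean is
exactly γ* = 50) carries its own state: a mean vector μ built from a shared
log-normal baseline (meanlog ln 0.2, sdlog 1.5 — a heavy-tailed abundance
profile typical of variable-feature panels) with state-specific
fold-changes (log-uniform in [2, 8]) on a random 10 % of features, making
states well separated.  Biological variation enters as per-feature
multipliers θ ~ Gamma(σ, 1/σ) (mean 1, σ = 5) drawn once per metacell,
optionally coupled across features by an equicorrelated-block Gaussian
copula (independent by default).  All cells of a metacell share
λ ∝ μ·θ; counts are Poisson(ω_i · μ_j · θ_j) with a per-cell amplification
factor ω_i ~ log-normal(0, 0.4) producing realistic library-size spread
(marginally each feature is Negative Binomial).  Conditional on library
size this is exactly the multinomial null, so ground-truth metacells are
trustworthy by construction; `make_mixed_partition` manufactures truly
dubious metacells as 50/50 merges of halves of two distinct-state
metacells, and `oracle_partitioner` provides partitions whose purity elbow
sits exactly at γ*.

What the generator does **not** emulate: fitted reference-data parameters
(means and dispersions are specified, not estimated), per-feature
dispersion profiles (σ is constant), empirical copula structure between
features, doublets/ambient RNA, and batch effects.  Passing tests therefore
demonstrate correctness of the statistical machinery under the model's own
assumptions, not robustness to everything real data can do.

## Problem sizes and tolerances used in the tests

Detection accuracy is evaluated on five replicate simulations of 2,000
cells × 1,000 features (40 true metacells), with 20 % of metacells mixed
for the main check and 10 % mixed plus a wider amplification spread
(sdlog 0.7, ≈20-fold range) for the wrong-null baseline; the granularity
sweep uses 1,500 cells × 600 features over γ ∈ {10, 25, 50, 75, 100}.
Monte-Carlo oracle checks use totals chosen so the standard error is an
order of magnitude below the asserted tolerance.  Exact identities
(permutation conservation laws, the Score identity, cTET worked examples)
are asserted exactly.

## Known limitations

* The null calibration rests on the stratified permutation preserving
  feature marginals; with very few features (p ≲ 20) pairing becomes coarse
  and the null noisy.  The method is intended for HVG-scale panels
  (p ≈ 1000–2000).
* The *magnitude* of the within-feature-only baseline's failure (how many
  purity-1 metacells it falsely flags) depends on the library-size spread,
  the number of metacells, and the feature-abundance profile; on our
  generator at the sizes above it is ≈25–35 %.  Its direction — gross
  over-flagging relative to ≤5 % nominal — is stable everywhere we tested.
* Detection treats cells as exchangeable within a metacell; it has no
  concept of ordered (e.g., developmental) within-metacell variation, which
  would be flagged as dubiousness.
* `baseline_partitioner` is deliberately simple; Score comparisons between
  *methods* are only as meaningful as the partitioners plugged in.
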