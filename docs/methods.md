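# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `fcmotif`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Network construction

A subject is a T×N matrix of voxel time series (N = in-mask voxels,
columns ordered by the fixed 0-based row-major linearization over
(x, y, z); every downstream vector inherits this ordering, which is what
aligns features across subjects). Each series is min-max rescaled to
[−1, 1] before correlation; the map is affine, so Pearson correlations are
unchanged — the rescaling is retained as a preprocessing convention, not a
numerical necessity. The N×N correlation matrix is computed from
standardized columns in row blocks (default 1024 columns) so peak memory
stays bounded; the result equals the direct pairwise formula to ~1e−15.

Conventions the correlation/thresholding layer fixes:

- **Strict thresholding.** An edge requires r > τ (resp. r < −τ,
  |r| > τ). Strictness matters only on sets of measure zero but makes the
  τ-sweep unambiguous.
- **Zero-variance voxels.** The correlation denominator vanishes; such
  voxels get r = 0 against everything, are listed as degenerate, and never
  abort a subject (masked-in dead voxels occur in real data).
- **τ domain** is the open interval (0, 1); modes are positive, negative,
  absolute. Default experiment: positive mode, τ = 0.80 — the combination
  that performed best on real multi-site data. Synthetic experiments use
  τ = 0.70, the midpoint of the generator's two coupling targets (below).

## Feature maps

- **Degree**: row sums of A. **Varying-distance degree**: edge lengths are
  voxel-center Euclidean distances in mm (voxel size × integer-coordinate
  distance; no anisotropy support); bins are right-closed intervals
  (l_{i−1}, l_i] over thresholds 20/40/80 mm, plus a final "> 80 mm" bin,
  so the bins partition the edge set and per-voxel bin counts sum exactly
  to degree.
- **Cycle counts** count each undirected simple cycle once per
  participating node: closed walks from the adjacency powers are corrected
  for degenerate walks and halved for traversal direction
  (L = 3: diag(A³)/2; L = 4: [diag(A⁴) − deg² − Σ_{a∈N(v)}(deg(a)−1)]/2).
  An exhaustive DFS oracle (count closed simple paths, divide by 2) defines
  the semantics for any L ≥ 3 and is the reference the closed forms are
  tested against on hundreds of random graphs; closed forms beyond L = 4
  are out of scope.
- **Weight sums** treat every voxel pair as a weighted edge. Negative sums
  are reported as magnitudes so that absolute = positive + negative holds
  identically; with a threshold, only weights beyond it are summed (the
  τ-sweep protocol reuses the graph threshold as the weight threshold).

## PCA-LDA classifier

Feature vectors have dimension (selected voxels × components), typically
far above the cohort size, so training first projects onto the leading k
principal components of the training set. k defaults to 40 for small
(single-site) cohorts and 100 for large ones; k is silently capped at
min(n − 1, d) with a logged warning. The Fisher direction solves
S_W w ∝ μ⁽ᴬ⁾ − μ⁽ᶜ⁾ with S_W the pooled within-class scatter and S_B the
rank-one between-class scatter (these are the conventional definitions;
the objective J(w) = wᵀS_B w / wᵀS_W w is only maximized under them).
Numerical conventions:

- **Ridge on singular S_W**: ε = 1e−6 · trace(S_W)/k added to the diagonal
  when the solve fails — k can approach n − 1, where S_W is rank-deficient.
- **Decision rule**: w is oriented so the ADHD mean projects above the
  midpoint of the two projected class means; scores strictly above the
  midpoint are ADHD, ties go to control. Equal priors are assumed; no
  probability calibration.
- **LOOCV**: PCA *and* LDA are refit in each of the n folds, so the
  held-out subject never influences the mean, the basis, or the scatter.
- **Metrics**: ADHD is the positive class; detection rate is percent
  correct over both classes; ratios with zero denominators are NaN, never
  silently 0.

A Gram-matrix LOOCV path (`loocv_predictions_gram`) computes the identical
predictions from the n×n Gram matrix — Fisher LDA predictions are
invariant to the choice of orthonormal basis of the PCA subspace — at a
fraction of the cost when d ≫ n; the mask search uses it, and a test
asserts prediction-level equality with the canonical path.

## Useful-region-mask search

The volume is tiled into 5×5×5-voxel cubes from the grid origin (smaller
slabs at the high boundary; boundary cubes participate in sampling like
any other). Each of m iterations draws a subset (each cube kept with
probability p; empty draws are resampled up to 100 times, then error) and
scores it by LOOCV detection rate of the classifier trained on features
from the subset's voxels only. The top ⌈0.10·m⌉ subsets by accuracy vote
(ties at the accuracy boundary are broken toward earlier iterations, for
determinism under a seed); each region's probability is its occurrence
count divided by the number of voting subsets, and the mask keeps regions
with probability ≥ th. Defaults p = 0.40, th = 0.60, m = 500.

Two deliberate choices:

- **Inner scoring uses k = 10 PCA components** (separately from the final
  classifier's k = 40). The score's only job is a stable *ranking* of
  region subsets; on cohorts of tens of subjects a larger basis inflates
  the variance of the leave-one-out estimate without adding discriminative
  signal, and a noisy score blurs the top-10% selection. Masked-vs-unmasked
  comparisons on synthetic cohorts are evaluated with this same k = 10
  classifier, so selection and evaluation share one objective.
- **The mask is confined to the brain volume** (union of the subjects'
  anatomical masks): voxels outside every brain carry no features and do
  not belong in a region-of-interest mask.

Scoring is LOOCV on the mask-generation cohort itself — not a held-out
test set — which avoids test-set leakage. The searched mask is therefore
mildly optimistic about its own cohort; judging it requires fresh data (or
the synthetic ground truth). The search defaults to degree features; the
feature kind is a configuration knob, not a second algorithm.

Cluster summaries of a mask use 6-connected components and report centroid
(voxel and mm), size in mm³ (count × voxel volume), and per-axis
population standard deviation of member-voxel mm coordinates.

## Synthetic cohort generator

The generator exists so that every stage — network construction, features,
mask search, classification — is testable end-to-end with a known ground
truth. Design:

- The grid (default 15×15×15, 4 mm voxels) is tiled into 3×3×3-voxel
  *latent blocks*, each with its own smooth latent signal (white noise
  low-passed to the lowest 20% of Fourier bins, unit variance — emulating
  slow resting-state fluctuations after bandpass). A voxel observes
  α·s_block + noise, with α = noise_sd·√(ρ/(1−ρ)) so the expected
  within-block correlation is ρ.
- The latent tiling is deliberately finer than — and not nested in — the
  5³ search cubes: functional parcels do not align with an arbitrary
  tiling, and the ~125 resulting latent dimensions against 80 subjects are
  what make whole-brain feature vectors overfit relative to masked ones.
- Three planted 5³ cubes (face-neighbours of the central cube, all fully
  inside the ellipsoid anatomical mask, each covering exactly two latent
  block centers so the three carry equally strong signal) are
  *informative*: latent blocks centered there couple at 0.80 for controls
  and 0.60 for ADHD subjects, emulating locally reduced synchronization in
  the affected group. Everywhere else both classes couple at the
  class-independent background 0.70.
- The background sits midway between the class targets so irrelevant
  blocks are exactly as variable across subjects as informative ones: a
  variance-driven projection cannot separate them, and region selection
  has to use the labels — the situation the mask search exists for.
- Per subject and per block the realized coupling is jittered
  (sd 0.15, clipped to [0.02, 0.97]) around its target, emulating
  between-subject variability in connectivity strength. Without jitter a
  single informative block separates the classes perfectly and every
  region subset containing one scores ~100%, leaving the top-10% selection
  without a ranking signal; with it, detection rates land in the 65–95%
  band and accuracy grades with the number of informative cubes included.
- Labels are balanced (controls first), the anatomical mask is an
  ellipsoid with semi-axes 0.52 × the grid dimensions (so boundary cubes
  are partially in-brain, as with a real volume), and everything is
  deterministic under the seed.

What the generator does *not* emulate: scanner physics, head motion,
hemodynamics, multi-site batch effects, spatial autocorrelation beyond the
block structure, or graded (non-cube) region boundaries. Passing tests on
this cohort show the chain recovers a planted, spatially confined coupling
difference under realistic sampling noise — not that it would succeed on
any particular real data set.

On this design, recovery at the published search settings (p = 0.40,
m = 100, top 10%, th = 0.60, τ = 0.70) is stochastic across cohorts: the
acceptance tests assert a median Jaccard ≥ 0.5 against the planted cubes
and a non-negative mean masked-minus-unmasked LOOCV margin over five
seeded cohorts, and `scripts/acceptance.py` recomputes both from scratch
for any seed. Individual seeds fluctuate (false-positive cubes arise from
chance class correlations that are real within a finite cohort); the
aggregate statements are the stable ones.

## Pipeline and problem sizes

`run_experiment` executes simulate/load → correlation → graph → features →
mask search → LOOCV evaluation, reporting metrics overall and per
acquisition site, and caches per-subject feature maps keyed by the
parameters that produced them (changing τ invalidates graphs and features
but not scans). Reports are byte-identical across reruns of the same
configuration and identical between the NIfTI-file CLI path and the
in-memory API path.

Default problem sizes were chosen to exercise every code path at desk
scale: 15³ grids (~1900 in-brain voxels, N×N correlation in well under a
second), 80-subject cohorts, m = 100 search iterations in tests (the
m = 500 default remains for real use). The real-data grid (49×58×47,
~28,000 in-brain voxels) is supported by the blocked correlation and
O(N³-free) feature computations but is not exercised in the test suite.

## Known limitations

- No preprocessing (motion correction, bandpass, smoothing, registration,
  scrubbing): inputs are assumed preprocessed and grid-aligned.
- Binary ADHD-vs-control only; no subtype output, no phenotypic
  covariates, no site harmonization.
- Cycle closed forms stop at L = 4; the enumeration oracle is exponential
  and only suitable for small graphs.
- Dense N×N matrices: memory is O(N²); the 28k-voxel real grid needs
  ~6 GB per correlation matrix in float64.
- The mask search scores subsets on the same cohort it votes with;
  population-level validity of a mask needs independent data.
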