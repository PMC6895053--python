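# Methods

This note records the models implemented in `emomap`, the assumptions
and parameter choices behind them, what the synthetic generators do and
do not emulate, and the numerical conventions a user should know before
trusting (or extending) a result.

## Rating preprocessing

Continuous ratings arrive as T×E matrices in [0, 100] at a native rate
(10 Hz in the emulated design). Preprocessing, in order:

1. **Downsampling** to the scanner TR (default 2 s) by *block mean* over
   each TR, not decimation — robust to native-rate jitter and consistent
   with the later smoothing.
2. **Hemodynamic lag** (default 2 s) as an integer-TR shift of the
   *alignment*: rating sample *i* predicts scan volume *i + lag/TR*. The
   sample values are untouched; only the volume bookkeeping moves. No
   hemodynamic response convolution is applied anywhere — delay is
   modeled purely as this lag.
3. **Smoothing** by a centered moving average (default 10 s = 5 TRs)
   with shrinking windows at the edges (no NaN padding).
4. **Edge trimming** (default on): the (w−1)//2 samples at each end
   whose smoothing window was incomplete are dropped. Matched against a
   scan, this convention reproduces the usable-sample count of the
   emulated design: a rating series covering a 3599-volume TR-2s scan
   yields 3595 usable samples at lag 2 s / window 10 s.

## Inter-rater agreement and its null

Agreement per emotion is Spearman ρ (midrank ties) over all
n(n−1)/2 subject pairs. Pairs involving a zero-variance rater are
recorded as missing, never as 0. The null distribution comes from IAAFT
surrogates of the group-average series: ρ between successive
(independent) surrogates gives a null agreement sample. An emotion is
"consistent across all subjects" when every defined pair exceeds the
null 95th percentile; the group-mean ρ additionally gets a permutation
p against the same null.

### IAAFT surrogates

The Iterative Amplitude Adjusted Fourier Transform alternates (a)
imposing the source's amplitude spectrum on the current surrogate's
phases and (b) rank-remapping onto the source's sorted values, until the
spectral mismatch stops decreasing (tolerance 1e-12, max 200
iterations). Ending on the rank remap makes the amplitude distribution
of every surrogate *exactly* that of the source. At the algorithm's
fixed point a residual spectral discrepancy remains — for a 1000-point
AR(1) series the relative L2 amplitude error plateaus around 4e-3, a
known property of IAAFT, not an implementation artifact. The package
therefore treats *spectral correlation* as the match criterion (power
spectra correlate with the source at 1 − r ≈ 1e-5; the type contract is
r > 0.99) and reports the L2 diagnostic alongside. Each surrogate draws
from an independent substream of the seed.

## Emotion dimensions (PCA)

PCA is computed by SVD of the mean-centered (never rescaled) group
ratings — covariance, not correlation: all emotions share the 0–100
intensity scale, and an overall-intensity component only exists if scale
is preserved. All C = E orthonormal components are returned; explained
variances are raw variance shares (eigenvalue / trace). Sign convention:
each loading column is flipped so its largest-magnitude entry is
positive. Components with singular values at numerical rank tolerance
are flagged degenerate.

**Leave-one-out consistency.** For each left-out subject, PCA runs on
that subject's ratings and on the average of the others; the left-out
scores are matched to the others' by orthogonal Procrustes (rotation and
reflection only — no scaling, no translation beyond centering), and the
rotated per-subject components are compared pairwise across subjects by
Spearman ρ, exactly like the raw emotions. The null passes surrogate
rating matrices through the same PCA machinery. Note an exactness
caveat established during development: if every subject is the *same*
orthogonal rotation of a common score matrix, post-Procrustes agreement
is exactly 1; with *distinct* per-subject rotations the leave-one-out
reference (PCA of a mean of differently-rotated matrices) is a
non-orthogonal mixture and exact recovery is mathematically impossible.
Recovery of a single known rotation against a fixed reference is exact.

## Affective-state clustering

Timepoints whose summed emotion intensity reaches the 50th percentile
are embedded by Barnes–Hut t-SNE (perplexity 30, angle θ = 0.05, PCA
initialization, seeded) and partitioned by k-means (10 restarts); k is
chosen by the silhouette criterion on the embedding over k = 2…20. The
perplexity imposes kept > 3·perplexity samples; smaller kept sets are
rejected with an explicit message.

## Voxelwise encoding

Ordinary least squares per voxel, intercept always included and never
counted in P. Predictors are z-scored by default so β magnitudes are
comparable across dimensions (required by the topography module); this
never changes the full-model R², which is invariant under any invertible
recombination of the predictors (tested to 1e-10). Condition numbers
above 1e8 warn; exact singularity raises. Zero-variance voxels get
R² = NaN and a flag, never a silent 0.

**Permutation inference.** Each null model replaces *all* predictor
columns jointly by independent IAAFT surrogates and refits;
p = (1 + #{null R² ≥ observed}) / (n_perm + 1) per voxel (the
+1-corrected ≥ convention), Benjamini–Hochberg FDR across voxels
(report q < 0.01). Joint surrogacy is the right null for a full-model-R²
statistic. Reference scale is 10,000 permutations; the calibration
studies use 500, which is already uniform to KS precision.

**Bootstrap SE.** Circular block bootstrap of timepoints with block
length ≈ √T, resampling design and activity jointly, SE = sd of R² over
iterations (default 1000; studies use 100–200). Blocks respect the
temporal autocorrelation that an i.i.d. bootstrap would destroy.

**Noise ceiling.** Lower bound: for each subject, fit the model on the
mean activity of the *others* and score the squared Pearson correlation
between prediction and that subject's activity (mean over voxels and
subjects). Upper bound: the same with the subject included in the mean.
On simulated shared-signal panels the true-model R² falls inside
[lower, upper] (50/50 runs in development checks).

## The topography statistic

For an ROI of N ≥ 4 voxels, two N×N dissimilarity matrices are compared
by Spearman ρ over their condensed upper triangles (diagonal excluded):

* anatomical — Euclidean distance of voxel centers in mm, or Dijkstra
  shortest paths over an edge-length-weighted cortical mesh graph;
* functional — Euclidean distance of per-voxel β profiles (|Δβ| for a
  single dimension).

Ranks use midranks throughout: lattice anatomy produces exactly tied
distances, and ordinal ranking would bias comparisons between
lattice-tied observed maps and continuous null maps.

**Null ensemble.** Null β are produced by refitting the encoding model
with IAAFT-surrogate predictors on the *real* activity — never by
shuffling β — so the null inherits the data's spatial autocorrelation;
p = (1 + #{null ρ ≥ ρ}) / (n_null + 1). A consequence verified in the
recovery studies: because the null is *deliberately* spatially
structured, testing a position-shuffled observed map against unshuffled
nulls is conservative at any SNR. The shuffled-control study therefore
applies the same voxel permutation to observed and null maps, restoring
exchangeability (measured rejection 3% at α = 5%); the companion
calibration check draws the observed map itself from a surrogate refit.

**Confidence intervals** are 2.5–97.5 percentiles over bootstrap
resampling of voxels (both matrices subset to the resampled voxel set;
duplicate voxels contribute tied zero distances, which midranks absorb).
The bootstrap unit is voxels, an assumption — timepoint bootstrap would
require refitting and answers a different question.

**Radius sweep** (9–27 mm reference range): the significant radius
(p < α) with the highest ρ wins; exact ties go to the smaller radius;
with no significant radius the selection is empty but all per-radius
statistics are returned. Sphere membership uses voxel centers with an
inclusive boundary (≤ radius, with a 1e-9 relative tolerance against mm
rounding).

**Gradient field.** Per-voxel numerical gradient of a β map over the
ROI lattice: central differences where both axis neighbors are in the
ROI, one-sided at the boundary, NaN where no neighbor exists; units β
per mm. The principal direction is the normalized vector sum of the
field — appropriate for linear gradients — with a null flag when the sum
vanishes (constant maps).

**Rotation analysis.** Rotations are sampled uniformly over SO(3)
(quaternion sampling, proper rotations only, seeded); for each, the
(N, 3) β matrix is post-multiplied and the per-dimension ρ recomputed;
the unrotated solution is ranked by mean per-dimension ρ among all
n + 1 solutions. Because the sampling is Monte-Carlo, rank conclusions
carry Monte-Carlo error of order n⁻¹.

A structural fact uncovered while designing the recovery study: *purely
linear* gradient maps plus isotropic β noise are closed under rotation
of the dimension basis — every rotation yields another set of linear
maps with an equivalent per-column SNR profile — so no rotation test can
single out the planted basis under that generator. The generator's
rotation-study condition therefore plants *saturating* (tanh) response
profiles (saturation length 1.5 mm at 9 mm radius — each map is
effectively a bipolar "hemifield" split, mirroring how bipolar dimension
maps look in practice); single-axis saturating fields are not closed
under rotation, and the unrotated solution then genuinely dominates
(identity rank 1–2 of 2001 across seeds).

**Geodesics.** Dijkstra on the undirected mesh graph with Euclidean
edge lengths (scipy csgraph); unreachable pairs yield +inf and a
`disconnected` flag. Plane meshes alternate the cell-split diagonal in a
checkerboard so both diagonal directions exist; graph distances for
well-separated pairs then exceed Euclidean by at most ~8% (the octagonal
metric bound), against 41% for a single-diagonal grid.

## pRF tuning

The tuning curve of a voxel along a dimension score s(t) is Gaussian:
regressor g(t) = exp(−(s(t) − μ)² / 2σ²). The grid spans μ from the 5th
to the 95th percentile of the scores at step 0.5 and σ from 1 to 12 at
step 0.25 (σ in raw score units — an assumption worth revisiting when
dimension scores differ wildly in variance). Per voxel the winning
(μ, σ) maximizes the simple-regression t = β/SE(β) (intercept included);
t is invariant to affine rescaling of the voxel's activity. Exact ties
resolve to the smallest σ, then the smallest μ — the most specific
tuning, deterministically. Degenerate regressors (constant over the
observed scores) contribute t = 0.

**Flat flag.** A voxel is flagged untuned when its best t does not
exceed the 95th percentile of its own null best-t distribution, obtained
by repeating the full grid search on IAAFT surrogates of the score
series (default n = 19 in studies, configurable). All-NaN voxels are
flagged and skipped.

**Recovery conditions.** "Activity SNR" in the recovery studies is the
temporal sd of the noiseless tuned response divided by the noise sd —
the variance-ratio definition; at SNR 2, ≥ 99% of planted μ are
recovered within one grid step.

**NMF.** Negative t values are clipped to zero (a "no response" stays
zero, keeping the parts-based reading) and the V×(μ·σ) matrix is
factored at rank 10 by multiplicative updates from seeded random
non-negative starts, 10 restarts keeping the lowest reconstruction
error. Components are ordered by variance explained (‖wᵢhᵢ‖²/‖X‖²);
a warning fires if total retention falls below 90%. Tuning curves
average the basis over all σ at each μ; components under 5% of variance
are excluded from the curves.

## Attribution models

Third-person series (22 categories, non-negative) get the exact same
lag/smoothing pipeline as the ratings (delegated column-wise to the same
function). Shared variance with the subjective model is 100·ρ²
(squared Spearman) per common category (happiness, fear, sadness,
anger), summarized as mean ± sd — the variance-partition formula is an
assumption, chosen because ρ is the only correlation the two rating
scales support. CCA uses centering, whitening by the truncated inverse
square root of each block's covariance (rank deficiency loses the null
space rather than exploding; an optional ridge is available) and SVD of
the whitened cross-covariance; canonical correlations are clipped to
[0, 1]. The half-run-split cross-validation fits on half of the runs and
evaluates on the other half, averaging both directions; it reports both
the squared Pearson correlation between prediction and observation
(non-negative, comparable across model dimensionalities) and the raw
1 − SSE/SST (which can go negative).

## What the generators emulate — and what they do not

The rating generator produces AR(1) Gaussian latents (unit marginal
variance, coefficients 0.8–0.9 at TR resolution) affinely mapped to the
0–100 scale (offset 50, scale 15), shared across raters, plus
independent per-rater Gaussian noise, clipped to bounds; the clipped
fraction is logged because heavy clipping distorts the spectra the IAAFT
null relies on (defaults keep it well below 1%). Voxel grids are
axis-aligned and isotropic (3 mm default) with mm voxel-center
coordinates; planted β maps are linear (or tanh-saturating) in the
projection onto unit directions, plus optional Gaussian β noise. BOLD
activity is β·designᵀ plus white Gaussian noise; the weak-signal study
regime (noise sd 60 against unit-variance designs and mm-scale β) puts
per-voxel R² near 0.04, matching naturalistic-fMRI effect sizes.

Not emulated: hemodynamic response convolution (delay is a lag by
design), head motion and physiological noise, spatially correlated
scanner noise, cortical folding in the volumetric analyses (the mesh
path exists for that), inter-subject anatomical variability, and rating
nonstationarities. Passing recovery studies therefore demonstrates the
*statistical machinery* is correct and calibrated under realistic SNR
and autocorrelation — not that real cortical emotion gradients exist;
that question needs real data.

## Seeds and reproducibility

Every stochastic routine takes a seed and fans it out to independent
substreams via `numpy.random.SeedSequence.spawn` (studies hash a string
label with CRC32 into the spawn key); regeneration from the same
(spec, seed) is bit-identical. Study sizes (100 runs × 100 nulls for
topography recovery, 500 permutations for calibration, 2000 rotations,
200 tuned voxels) were fixed once as the package's desk-scale defaults;
reference-scale counts (10,000 permutations, 1000 nulls, ~70,000
rotations) are plain parameter changes.

## Known limitations

* The spectral match of IAAFT surrogates is approximate at the fixed
  point (see above); tests that need an exact distribution use the
  sorted-values contract instead.
* The voxel-bootstrap CI treats voxels as exchangeable units; spatially
  correlated β noise would make it optimistic.
* The gradient-field principal direction assumes an approximately linear
  field; curved gradients need the full vector field, which is returned.
* `radius_sweep` refits nothing — it trusts its `beta_provider`; sweep
  results are only as unbiased as the provider's independence from the
  selection step.
* t-SNE embeddings are seeded but remain sensitive to perplexity in
  borderline cluster-separation regimes; the silhouette selection is
  evaluated on the embedding, inheriting that sensitivity.
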