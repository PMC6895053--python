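# emomap

Topographic analysis of emotion dimensions in functional neuroimaging:
from continuous emotion ratings, through voxelwise encoding models, to
the detection and characterization of orthogonal, spatially overlapping
emotion gradients ("emotionotopy") in a cortical region of interest.

## The problem

Observers can continuously report the perceived intensity (0–100) of
basic emotions (happiness, surprise, fear, sadness, anger, disgust)
while watching a naturalistic stimulus. Principal component analysis of
such ratings yields a small number of orthogonal *emotion dimensions* —
a polarity (pleasant vs unpleasant), a complexity (cognitively mediated
vs automatic) and an intensity axis. The emotionotopy hypothesis holds
that these dimensions are mapped onto cortex as *gradients*, the way
retinotopic maps encode eccentricity and polar angle: voxels with
similar functional profiles should lie close to each other.

The package implements the full chain needed to test this on data with
known ground truth:

1. **ratings** — block-mean downsampling to the scanner TR, hemodynamic
   lag, moving-average smoothing; inter-rater agreement (Spearman ρ over
   all subject pairs) against IAAFT surrogate nulls; PCA dimensions with
   leave-one-subject-out Procrustes consistency; t-SNE + k-means
   affective-state clustering with silhouette-selected k.
2. **encoding** — per voxel, OLS regression of activity *y(t)* on the
   emotion design *X* (intercept always included); the full-model *R²*
   is tested against 10,000-style null models in which every predictor
   is replaced by an IAAFT surrogate (same spectrum and amplitude
   distribution, no relation to the data), with Benjamini–Hochberg FDR
   across voxels, circular-block-bootstrap standard errors, and a
   leave-one-subject-out noise ceiling.
3. **topography** — the core statistic: Spearman ρ between the condensed
   upper triangles of two inter-voxel dissimilarity matrices over a
   spherical ROI — anatomical (Euclidean mm, or Dijkstra geodesics along
   a cortical mesh) vs functional (Euclidean distance of encoding-β
   profiles). Significance comes from β ensembles refit from surrogate
   predictors on the real activity, so the null inherits the data's
   spatial autocorrelation. Plus: 9–27 mm radius sweeps, numerical
   gradient fields and their summed principal direction, and a
   rotated-solution analysis ranking the unrotated dimension basis among
   thousands of random rotations.
4. **prf** — per-voxel Gaussian tuning (preferred score μ, width σ) by
   exhaustive grid search (μ over the 5th–95th score percentiles, step
   0.5; σ from 1 to 12, step 0.25; ≈5k combinations), selecting the
   highest regression *t* = β/SE(β); NMF decomposition of the t-value
   grid into prototypical tunings.
5. **attribution** — third-person portrayed-emotion models (22
   categories): preprocessing parity, shared variance (100·ρ²) on the
   four common categories, CCA alignment into the subjective-dimension
   space, half-run-split cross-validated model comparison.
6. **synthetic** — seeded generators for every input: multi-rater
   autocorrelated bounded ratings sharing latent components, voxel ROIs
   with planted linear or saturating gradients, Gaussian-tuned voxels,
   BOLD-like forward models, and plane/sphere meshes.

## Worked example

The numbered drivers under `analysis/` run the pipeline end-to-end on
synthetic data and write tables under `results/`:

```bash
python analysis/01_simulate_ratings.py --seed 1
python analysis/02_emotion_dimensions.py --seed 1
python analysis/03_encoding.py --seed 1
python analysis/04_topography.py --seed 1
python analysis/05_prf_tuning.py --seed 1
python analysis/06_attribution.py --seed 1
```

`analysis/02` prints, for a 12-rater panel driven by three latents:

```
12 raters, 66 pairs
emotions consistent across all pairs: happiness, surprise, fear, sadness, anger, disgust
PC explained variance (%): 51, 30, 19, 0, 0, 0  (first three: 100%)
affective states selected by silhouette: k = 2
```

Three components carry all the variance because exactly three latents
were planted; every emotion is consistent because the simulated raters
share them. `analysis/03` then fits the encoding model in a 15 mm ROI
(515 voxels at 3 mm) at a realistic weak-signal level:

```
mean R^2 = 0.042 +- 0.019 (SE); 276 voxels significant at q<0.01 (500 permutations)
noise ceiling: lower 0.037, upper 0.039 (5 simulated subjects)
```

A mean *R²* of ~0.04 with a tight noise ceiling around it is the
expected signature of the weak-but-reliable regime the generator
emulates. `analysis/04` then detects the planted gradients through the
topography statistic (coefficients refit from that weak-signal
activity, 200 surrogate-refit nulls, 200-voxel-bootstrap CIs):

```
full-profile topography rho = 0.682, p = 0.005, 95% CI [0.661, 0.709]
  dim1: rho = 0.246, p = 0.005, direction error 8.3 deg
  dim2: rho = 0.352, p = 0.005, direction error 3.5 deg
  dim3: rho = 0.388, p = 0.005, direction error 1.8 deg
```

Each planted dimension is individually significant against the
autocorrelation-preserving null and its gradient direction is recovered
to within a few degrees. `analysis/05` recovers planted Gaussian
tunings:

```
mu recovered within one grid step: 99.0%
tuning-vs-gradient rho = 1.000 (p = 0.001)
NMF rank 10 retains 97.4% of variance
```

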