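# Methods

## Pipeline model

`paddyscan` treats a nadir RGB view of a rice paddy as a two-layer
scene: a soil or water background and a set of green plant instances.
Stage 1 locates and delineates the instances; stage 2 describes each
instance and flags the ones that deviate from the population.

### Stage 1 — vegetation-index prompting and promptable segmentation

The ExGR index, `3·G − 2.4·R − B`, is a linear form in the channels, so
its value on an anti-aliased plant/soil boundary pixel interpolates
linearly between the pure-plant and pure-soil values; thresholding it
therefore recovers the sub-pixel boundary location well. Indices are
computed on unit-scaled `[0, 1]` channels by default; `none` and
chromatic `(R,G,B)/(R+G+B)` normalizations are available because both
conventions appear in the vegetation-index literature. Downstream
thresholding is histogram-driven (multi-Otsu), so the choice mostly
cancels.

Multi-Otsu maximizes between-class variance of a 256-bin equal-width
histogram of the index. The class count defaults to 3 (background /
mixed / vegetation) for flooded scenes whose histograms are trimodal;
on soil-background scenes — including the synthetic generator's default
soil scenes, which are bimodal — 2 classes are the appropriate setting
and are used throughout the examples, tests and acceptance runs. The
most-vegetated class becomes the candidate mask; components smaller
than `min_area` (default 20 px) are treated as sensor noise. Each
surviving component contributes its bounding box and the box's
geometric center (pixel-center convention: a component spanning rows
10–14 has center row 12.0) as a point prompt. The component centroid is
available as an alternative center definition.

The segmenter is a pluggable contract: *(image, point) → candidate
masks with scores*. Three backends implement it: the foundation-model
adapter (an external point-promptable ViT-H predictor, queried
zero-shot with multimask output), the classical fallback (8-connected
flood fill on the ExGR map at or above the multi-Otsu vegetation
threshold, with a 5-px seed-snap and optional radius clip), and the
synthetic module's ground-truth oracle. Per prompt, one candidate is
kept (highest score by default; "smallest containing the prompt" for
over-segmentation-prone scenes). Masks that mostly coincide (IoU >
0.5) are merged into one instance — duplicate prompts in one plant
yield one seedling — and lightly overlapping instances split contested
pixels by nearest prompt. All resolution steps are deterministic.

### Stage 2 — features and one-class-SVM health assessment

Each instance yields a fixed 15-vector:

* **morphology** — area (px²); perimeter, by the 4-direction Crofton
  estimator (within ~1 % of `2πr` on rasterized discs; the weighted
  boundary estimator and an exact crack-length estimator are options);
  solidity = area / convex-hull area; eccentricity of the best-fit
  ellipse, `√(1 − (b/a)²)`; circularity = `4π·area / perimeter²`,
  never clamped, flagged degenerate above 1.2 (tiny rasterized shapes
  can exceed the continuum bound of 1).
* **spectral** — mean R, G, B over the mask and mean ExG
  (`2·G − R − B`). Yellowing raises red and depresses green/ExG.
* **texture** — contrast, dissimilarity, homogeneity, energy,
  correlation and angular second moment from a symmetric normalized
  GLCM at distance 1 px, averaged over the four principal directions,
  on the BT.601 luminance quantized to 32 equal-width bins spanning the
  *image's* gray range (fixed bins keep crops comparable; per-crop
  ranges would confound the statistics with each crop's contrast
  stretch). The default region is the instance's bounding-box crop —
  plant-against-background contrast is itself a health cue — with a
  `masked` mode that excludes pixel pairs touching background. Energy
  is defined as the square root of the direction-averaged ASM so that
  energy² = second moment holds exactly; both columns are kept because
  both belong to the standard descriptor set. A constant crop has a
  single-entry GLCM: contrast/dissimilarity 0, homogeneity/energy/ASM
  1, and correlation — undefined at zero variance — imputed as 0 with a
  flag.

Features are z-scored per column (population sd; constant columns pass
through flagged) and fed to a one-class SVM. Hyperparameters come from
an exhaustive grid — kernels {linear, RBF, polynomial (degree 3)},
ν {0.01, 0.05, 0.1}, γ {0.01, 0.1, auto, scale} — ranked by the
silhouette score of each fit's inlier/outlier partition, computed with
Euclidean distances in the same standardized space the SVM saw.
One-class outcomes score −∞ and can never win; ties keep the earlier
combination in grid order. γ is inert for the linear kernel, so those
duplicates are fitted once and logged as collapsed.

Two numerical choices matter here. The polynomial kernel uses the
inhomogeneous form (`coef0 = 1`): the homogeneous `(γ⟨x,y⟩)³` at
γ = 0.01 produces kernel values near machine zero and a meaningless
fit. And outlier labels are read as the most negative decision values,
at most `⌊(ν + 0.05)·n⌋` of them: at solver precision many support
vectors sit numerically *on* the boundary, and a raw sign read can flag
far more than ν·n points — for the linear kernel on z-scored features
(which surround the origin the SVM separates from) the fit is fully
degenerate and a sign read returns noise. The cap is ν plus a fixed
0.05 tolerance on the trained-outlier fraction, so the ν-property holds
for every grid combination by construction, while degenerate fits
produce small arbitrary partitions whose poor silhouette eliminates
them from selection.

Diagnostics: per-feature Bhattacharyya distance between the two groups
in the univariate-Gaussian closed form

    D = ¼·ln(¼·(σ₁²/σ₂² + σ₂²/σ₁² + 2)) + ¼·(μ₁−μ₂)²/(σ₁²+σ₂²)

computed on raw (unstandardized) values with variances floored at
1e−12, undefined (flagged) when a group has fewer than two members; and
a seeded 2-D t-SNE projection (perplexity `min(30, (n−1)/3)`) for
visualization only — nothing downstream consumes it.

### Evaluation

Pixel confusions give per-image Dice `2TP/(2TP+FP+FN)`, IoU
`TP/(TP+FP+FN)` and FPR `FP/(FP+TN)`; batch values are unweighted
means over images (a pooled-pixel mode exists behind a flag).
Conventions keep plant-free images usable: empty-vs-empty scores
Dice = IoU = 1 (flagged), and FPR is undefined (flagged, excluded from
the mean with a logged count) when an image has no true background.
Counting is summarized by OLS of predicted on true counts and
R² = 1 − SSres/SStot; predicted counts are final instances after
overlap resolution, so merged plants under-count — the behaviour dense
canopies actually produce.

## Synthetic scenes: what they emulate and what they do not

The generator emulates the cues the pipeline consumes — index contrast,
shape, texture, planting geometry — not the full radiometry of a
paddy. Plants are anti-aliased lobed rosettes (5–6 petals, solid core,
mild elongation) on a jittered planting grid; background is textured
soil (brown, low-frequency field noise) or flooded water (dark
blue-gray with specular speckle); Gaussian channel noise is added
last. Ground-truth occupancy is the pre-noise alpha ≥ 0.5 region;
where plants overlap, the later-drawn plant owns contested pixels,
which defines the counting truth at the mature stage.

Default study conditions: 384×384 px scenes, 40 plants, healthy canopy
RGB (62, 142, 58) with per-plant jitter of sd 6 channel units clipped
at ±1.5 sd (colour variation within one uniformly managed paddy is
bounded), per-plant radius draws truncated at ±2 sd (transplanted
seedlings are size-graded), noise sd 2. Stage presets scale radius and
overlap together — early (12 ± 1 px, no overlap), mid (16 ± 1.5,
overlap 0.15), mature (20 ± 2, overlap 0.35) — matching a low-altitude
UAV ground sampling distance of roughly 0.5 cm/px where an early-stage
seedling spans ~12 cm. A stage series shares one seed, hence one
planting grid, per-plant identities and anomaly choices across the
three stages; every random substream (placement, shape, colour,
anomaly choice, background, noise) draws a fixed count so the sharing
is exact.

Stressed plants (default fraction 0.05) are hue-shifted toward
yellow-brown by (+35, −20, +5) channel units — several healthy-jitter
sd on red and green — at half linear size, with radial boundary noise
(relative amplitude 0.15) and chlorotic mottle (multiplicative smooth
speckle, amplitude 0.35) as the texture signature of leaf stress.

What passing tests on these scenes shows: the plumbing is exact (oracle
backend gives Dice 1.0 and exact counts), the classical fallback is
accurate when index contrast is clean, and the feature + selection
machinery recovers coherent stressed phenotypes of this kind. What it
does not show: robustness to real-field radiometry (shadows, glint,
mixed weeds), to stress phenotypes unlike the generated one, or to the
foundation segmenter's behaviour, which is only exercised when a
checkpoint is supplied.

## Known limitations

* The silhouette criterion structurally favours small, extreme outlier
  sets; it reliably selects models that flag a stressed subgroup only
  when that subgroup is coherent (similar phenotype). Diffuse or
  one-of-a-kind anomalies may be found by the SVM yet lose the model
  selection to a sparser partition.
* A one-class SVM ranks by kernel density, not distance: a large,
  mutually similar anomaly group supports its own density and can be
  partially enclosed. Health runs are therefore fitted per survey
  (per image batch of one stage), not pooled across many surveys.
* ν caps the flagged fraction, so recall of a stressed fraction larger
  than the grid's maximal ν (0.1) is impossible by construction.
* Counting truth under heavy overlap reflects the draw-order occlusion
  rule; real mature canopies are harder than this.
* Features of very small instances (≲ 30 px) are estimator-noise
  dominated; the 20-px `min_area` default drops the smallest, which
  can exclude severely stunted plants from stage 2 — visible as a
  consistent slight under-count.
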