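# Methods

## Registration model

The array is modeled as a rectangular lattice with five free parameters:
origin `o = (x0, y0)` (pixel position of grid node (1, 1)), anisotropic
pitches `(p_x, p_y)` (pixels per index step; anisotropy absorbs
non-square resampling), and a single rotation `θ` of the column axis,
the row axis being constrained perpendicular:

```
node(c, r) = o + R(θ) · ((c − 1)·p_x, (r − 1)·p_y),   c = 1..33, r = 1..35
```

Fitting minimizes the summed squared distance between observed blob
centers and their nearest grid nodes. Because the assignment is itself
unknown, the fit alternates (i) nearest-node assignment by derotated
rounding and (ii) parameter updates — for fixed θ the model is linear in
`(x0, y0, p_x, p_y)`, so the inner solve is an ordinary least-squares
problem and θ is found by bounded 1-D minimization around its initial
estimate. Alternation stops when the relative objective change falls
below 1e-8 (or after 200 alternations).

Initialization matters for an assignment-based fit: the pitch is
estimated as the median of 4-nearest-neighbor distances near the modal
1-px histogram bin (the single shortest distance is biased low under
center noise), rotation as the circular median of axial-neighbor
bearings folded into [0°, 90°), and the origin as the minimum corner of
the derotated cloud snapped to the lattice phase (circular mean of
coordinates modulo the pitch). Anchoring the origin on the raw minimum
point instead lets a single outlier below the lattice split rows across
index boundaries, from which the alternation cannot always recover.

### Iterative refinement

The first fit assumes up to 42 grid points per row and column. The
refinement loop then repeatedly removes `max(1, ⌈0.001·N⌉)` points with
the largest residuals (ties broken toward points farther from the grid
centroid, where stray artifacts live), refits, and recomputes the
occupied extents, until the layout equals the design target (33 × 35).
Two details make this robust:

* Occupied extents are counted on *unclipped* nearest-node indices, so a
  stray point beyond the array genuinely widens the extent; but for
  residual ranking, indices are clipped to the best contiguous
  target-sized index window (the one capturing the most points), so such
  points acquire near-pitch residuals and are shed first. Clipped points
  are excluded from parameter updates.
* Orientation is resolved by matching the larger target extent to the
  larger occupied extent, swapping axes and refitting when they
  disagree.

If points are exhausted before the targets are met, the run fails
through a typed error carrying the full iteration log for the QC report.

## Blob detection and lattice scoring

Spots are dark disks, so detection inverts the prepared channel, blurs
at σ = 3 px and computes the Hessian determinant, which peaks at blob
centers. Two non-obvious choices: the response is zeroed where the
Laplacian is non-negative (det(H) > 0 also at background *pits* between
spots, which otherwise double the detection count), and peak positions
are refined by per-axis quadratic interpolation followed by a
background-subtracted intensity centroid over a small window. At ~13.5
px pitch, integer-pixel maxima carry ~1 px median error — enough to blur
the separation between lattice and artifact scores — while refined
centers come in around 0.5 px.

Each candidate is scored against its 8 nearest neighbors. A neighbor
displacement `d`, derotated into grid axes, is compared to its nearest
integer lattice vector `L = (round(d_x/p)·p, round(d_y/p)·p)`: the
distance penalty is `||d| − |L||/p` and the angle penalty the angular
deviation between `d` and `L` normalized by 45°; a neighbor closer than
half a pitch has no lattice vector and draws the maximum penalty. This
formulation gives *exactly* zero to every point of a perfect lattice —
including diagonal and knight's-move neighbor vectors such as
(2, 1)·pitch, which any bearing-folding rule would wrongly penalize.
The default keep-rule retains blobs with mean combined penalty ≤ 0.25
(an absolute threshold; a percentile mode is available in `KeepRule`).
Under ≤ 2% lattice jitter, lattice points score well below 0.1 and
uniform clutter above 0.5, so the histogram is strongly bimodal and the
threshold is not delicate.

## Tissue masking

Background statistics (mean, sd) come from the 20-px border frame, where
no tissue is expected. "Stain" is defined as `1 − channel value` so that
darker stained pixels score higher; the primary mask is
`stain > stain_bg + k·sd` with k = 1. The polarity of the thresholding
rule is genuinely ambiguous for bright-field imagery; the dark-stain
convention is the one validated against the generator's ground truth
(mask-vs-polygon IoU ≥ 0.85 in the test suite). The border-connected
background found by flood fill (absolute tolerance 0.1 from all four
corners) is removed, two Gaussian blur + 0.5-threshold passes (σ = 10,
then σ = 1) erase spot-sized speckle and recover weak edges, and the
optional bubble mask captures pixels that are dark (< 0.35 in all three
channels) and near-gray (channel spread < 0.08). Bubble pixels are
removed from the tissue mask, keeping the two masks disjoint by
construction. Under-tissue calling tests the single rounded centroid
pixel of each node — resolution-independent and exactly the "node in
mask" rule the output table documents.

## Quantification estimators

* **Per-spot IF sums**: a patch of ±1% of the image extent per axis
  (floored to whole pixels) around each spot centroid, clipped at the
  borders, summed. Linear in the input by construction; inputs are
  expected background-subtracted (see footprint extraction).
* **Lateral diffusion**: each line profile is fit with a degree-5
  polynomial (on centered/scaled positions for conditioning); boundaries
  are the local minima of the fit flanking its global interior maximum
  whose fitted intensity exceeds 10% of the peak, nearest minima first
  when several qualify. Offsets are measured outward per side
  (footprint boundary beyond the nuclear boundary is positive,
  contained is negative) and converted at 0.1728 µm/px. Profiles whose
  fit has no qualifying flanking minima are rejected with a profile
  diagnostic rather than guessed at.
* **Footprint extraction**: Gaussian smoothing with σ = 1% of the
  longest image dimension (the relative reading of a dimensionless
  smoothing parameter; an absolute override exists), background by
  grayscale morphological reconstruction from a border-seeded marker,
  Sobel elevation map, watershed from low/high intensity quantile
  markers, optional tissue-mask restriction. SNR is the mean in-object
  signal over the mean out-of-object residual (floored at 1e-6); below
  3:1 an advisory flag recommends re-optimizing the tissue reaction.

## Saturation modeling

`fit_saturation` regresses 1/S on 1/R and maps slope/intercept to
(V_max, K_M); nonpositive slope or intercept means the data are not
saturating and the fit is refused. The linearization weights shallow
points heavily under noise, so an optional nonlinear refinement
(direct hyperbola fit seeded from the linear solution) is provided.
Downsampling is binomial thinning of per-molecule read multiplicities;
when only UMI-collapsed counts are available each UMI is treated as a
single-read molecule — a documented approximation that makes thinning
exact at the count level but cannot model read-level duplication.
Curves sample 9 log-spaced fractions over 1e-5..1 (0.001%–100%), and a
gene counts as expressed at a point when its surviving transcripts
exceed 1e-6 of that point's read depth.

## Synthetic data: what it emulates, and what it does not

The generator renders what drives the registration algorithm: dark
anti-aliased spot disks (contrast ≈ 0.37 against a 0.92 gray-white
background with per-pixel noise sd 0.008), an H&E-like tissue blob
(Fourier-perturbed ellipse, hematoxylin/eosin color mix, texture noise,
alpha 0.85 so spots beneath it disappear), multiplicative low-frequency
coloration (±8%), near-black bubbles, and smear patches. Smears are
labeled "pink" after the artifact class they mimic, and their stain
contrast is placed almost entirely in the red channel (darkening
R/G/B by 0.30/0.04/0.12): that is the configuration in which red-channel
masking picks smears up as false tissue and green-channel masking does
not, which is the behavioral asymmetry the channel option exists for.
Benchmark images use one tissue blob covering 20–40% of the grid area,
a coloration field, two smears and one bubble.

The generator does **not** attempt photorealistic histology: no optical
PSF, no chromatic aberration, no illumination gradients beyond the
coloration field, no nuclear-scale texture, and counts are Poisson
(zero-truncated per spot, multinomial across genes) rather than
read-level simulation. Passing the synthetic benchmark therefore shows
that the geometry pipeline is correct and artifact-tolerant under the
stated contrasts; it does not certify behavior on stains or scanners
whose contrast structure differs substantially.

Line-profile fixtures are built as exact quartics whose stationary
minima sit at the stated cell boundaries, so the degree-5 boundary
estimator has a well-defined truth to recover (exact at zero noise);
real profiles are rougher, and the noise-sd-0.02 recovery test (mean
absolute error < 1 px equivalent over offsets −5..+5 px) is the
meaningful statement about robustness.

## Problem sizes and determinism

Synthetic benchmarks run at ~14 px pitch (≈ 490 × 518 px canvases, 1,155
spots), one clean render plus ten artifact renders for the acceptance
script; a full registration takes well under a second on one CPU. All
randomness flows through `numpy.random.default_rng` seeds; identical
seeds give bit-identical images, matrices and traces.

## Package shape

The two estimation problems at the core — the regular-grid fit and the
saturation fit — follow the fit-function → results-object convention
(`GridFitResult`, `SaturationFit`, each with `summary()`); the
surrounding workflow (image preparation, masking, serialization, QC) is
a function pipeline with `register()` as the single entry point and a
thin click CLI on top, which matches how the tool is actually run.

## Known limitations

* Rectangular lattices only; hexagonal arrays are out of scope.
* Rotation recovery is validated for |θ| ≤ ~10°; the QC report warns
  beyond 10° rather than failing.
* The tissue mask is intensity-based; faint tissue at background
  contrast will be missed (and flagged via the under-tissue fraction
  warning) — no learned segmentation is attempted.
* `estimate_pitch` assumes a mostly-lattice blob population; images
  dominated by clutter fail through the grid-score filter's diagnostic
  rather than producing a grid.
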