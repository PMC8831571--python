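# spotgrid

Automated spot-grid registration for spatial transcriptomics (ST) array
images, plus the quantitative estimators that accompany array-based
protocols: per-spot immunofluorescence quantification, lateral-diffusion
measurement from line profiles, fluorescent cDNA footprint extraction,
and sequencing-library saturation modeling.

## The problem

Legacy ST arrays are glass slides printed with a rectangular lattice of
barcoded capture spots (here 100 µm diameter, 200 µm center-to-center
pitch, 33 columns × 35 rows, 1,007 barcoded positions). After an
experiment, the gene-by-barcode count matrix is only interpretable once
each barcode's (x, y) grid index is tied to a pixel position in the H&E
image of the tissue sitting on the array — including spots *hidden under
the tissue*, which are exactly the ones that matter. Doing this manually
is slow and error-prone; `spotgrid` does it automatically and robustly
against common imaging artifacts (uneven coloration, pink smears,
mounting bubbles).

## How it works

1. **Preparation** — downscale to ≈500 px, select a color channel,
   generously pre-mask the darkest 10% of pixels (tissue), crop 4 px of
   border.
2. **Blob detection** — isotropic blur (σ = 3), determinant-of-Hessian
   blob response, local maxima in a 3-px window with sub-pixel
   refinement.
3. **Lattice filtering** — each candidate is scored by how well its 8
   nearest neighbors agree with a regular grid (distance and angle
   deviation from the nearest integer lattice vector); off-lattice
   blobs are dropped.
4. **Grid fitting** — a parametric grid `node(c, r) = o + R(θ)·((c−1)p_x,
   (r−1)p_y)` is fit by alternating nearest-node assignment with least
   squares (90° axes assumed, 42 grid points per row/column initially);
   the worst-fitting 0.1% of points are shed per iteration until the
   occupied layout equals the 33 × 35 target. Every lattice node then
   has a coordinate, observed or not.
5. **Tissue masking** — background statistics from the outer 20-px
   frame, stain thresholding, border flood fill, two blur/threshold
   passes (σ = 10, then 1), optional bubble mask (dark, near-equal RGB);
   grid nodes under the mask are flagged `TRUE` in `output.tsv` and used
   to subset the expression matrix.

Sequencing saturation is modeled as the Michaelis–Menten hyperbola
`S = V_max·R/(K_M + R)` (S unique molecules at R raw reads), fit through
its Lineweaver–Burk linearization `1/S = (K_M/V_max)(1/R) + 1/V_max`;
the reads needed for a target saturation follow as
`R_s = S_s·K_M/(V_max − S_s)`.

A synthetic-array generator (`spotgrid.synthetic`) renders stained-array
images with exact ground truth — spot lattice, tissue polygon, artifact
inventory — so the whole pipeline is benchmarkable without any
downloaded data.

## Worked example

```python
import spotgrid as sg

art = sg.ArtifactConfig(tissue=True, coloration=True, n_smears=2, n_bubbles=1)
img, truth = sg.render_array_image(artifacts=art, seed=3)
res = sg.register(img, channel="green", use_bubble_mask=True)
print(res.summary())

score = sg.score_recovery(res.spots, truth)
print(f"FP {score.fp_rate:.2f}%  FN {score.fn_rate:.2f}%")
```

prints

```
Regular grid fit
========================================
points (surviving)          771
layout (cols x rows)     33 x 35
pitch x / y (px)        13.5140 / 13.5110
rotation (deg)           0.0004
origin (px)          (16.27, 16.32)
objective (SSR, px2)      78.07
rms residual (px)        0.3182
refine iterations             2

tissue mask pixels        77572
under-tissue spots          429 / 1155
QC status                  pass

FP 0.00%  FN 0.00%
```

The fit reached the full 33 × 35 layout from 771 lattice-consistent
blobs (spots under the tissue are not visible), the fitted pixel pitch
maps back to 200 µm through the rendering scale, 429 spots are called
under tissue, and every reported spot matches a true lattice position
within half a pitch (FP = FN = 0%).

The saturation side works the same way:

```python
data = sg.simulate_saturation_data(20000, 1e6, [2e5, 1e6, 5e6], 0.01, seed=2)
fit = sg.fit_saturation([sg.SaturationPoint(r, s) for r, s in data])
print(fit.summary())          # V_max ≈ 19806, K_M ≈ 986292 (truth 20000 / 1e6)
sg.reads_for_saturation(fit.model, 18000)   # ≈ 9.8e6 raw reads
```

The same operations are available from a shell via the `spotgrid` CLI
(`simulate-array`, `register`, `quantify-if`, `diffusion`, `footprint`,
`saturation`); `spotgrid register --image he.png --channel green
--bubble-mask --out out/` writes `output.tsv`, `report.json` and an
overlay figure, exiting 0 on pass and 2 on warn.

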