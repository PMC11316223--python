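# fibromorph

Automated morphotyping of fibroblasts from multi-channel fluorescence
microscopy, built for studies of the fibroblast-to-myofibroblast transition
(FMT) under contact guidance: cells cultured on linear fibronectin
micropatterns ("width × spacing" lines such as 20×20, 10×10 and 5×5 µm)
change shape, focal-adhesion (FA) architecture and phenotype, and those
changes can be quantified objectively from DAPI / F-actin / vinculin
images.

The package provides, end to end:

* **Preprocessing** — maximum z-projection, percentile autocontrast (0.35%
  saturated pixels by default) and white top-hat filtering of the FA
  channel to isolate vinculin puncta.
* **Three-level segmentation** — nuclei by two-class Otsu thresholding
  (σ²_b-maximizing scan with a fixed tie-break), cells grown from nucleus
  seeds by geodesic nearest-seed assignment over the actin foreground, and
  FAs thresholded *within* the cell masks with per-punctum parent
  assignment.
* **Morphometry** — a fixed, ordered catalog of 40 features per cell: 13
  shape descriptors each for the cell and its nucleus (area, chain-code
  perimeter, moment eccentricity *e* = √(1 − λ_min/λ_max), axis lengths,
  orientation, solidity, extent, form factor 4πA/P², compactness, Feret
  diameters), 13 FA aggregate summaries and the FA count.
* **Phenotype-axis normalization** — per-feature affine map placing
  condition means on the FMT axis, with the homogeneous-coating fibroblast
  control at n = 0 and the TGF-β-activated myofibroblast anchor at n = 1:
  n = (x̄ − x̄_ctrl)/(x̄_myo − x̄_ctrl).
* **Determinant ranking** — a seeded gradient-boosted classifier per
  condition-vs-control comparison, attributed with **exact interventional
  tree-Shapley values** (per-leaf closed form; matches brute-force subset
  enumeration to ≈1e-15) and ranked by mean |φ|; near-chance models are
  flagged so unreliable rankings are never silent.
* **Spatial statistics** — FA-centroid-to-own-nucleus-centroid distances
  (µm); cell orientation relative to the pattern direction (0° parallel,
  ±90° perpendicular, axial statistics via angle doubling); fiber
  orientation from multiscale Frangi vesselness + structure tensor, with
  the alignment order parameter S = |⟨e^{2iθ}⟩|.
* **Group statistics** — one-way ANOVA plus Dunnett many-to-one
  comparisons against the control (seeded Monte Carlo over the joint
  multivariate-t null).
* **Auxiliary assays** — pyramidal (Sneddon) Hertz fitting of AFM
  force–indentation curves, F = tan α/(√2(1−ν²))·E·(δ−δ₀)², jointly over
  E ≥ 0 and the contact point δ₀; and ΔΔCt fold changes
  (fold = 2^−ΔΔCt, GAPDH reference) for qPCR.
* **A synthetic-scene generator** with exact per-object ground truth
  (label masks plus analytic centroids, axes, orientations, eccentricities
  and areas), which is the package's test harness: segmentation and
  morphometry are validated by parameter recovery against it.

## Worked example

`examples/01_simulate_and_segment.py` renders a 175 µm field with 5 cells
(8 FAs each) at SNR ≈ 10 and segments it:

```
scene: 5 cells on a 175 um field, 0.25 um/px
  nucleus  true   5  recovered   5
  cell     true   5  recovered   5
  fa       true  40  recovered  40
per-cell Jaccard overlap with truth: min 1.000
```

Counts match the ground truth exactly and every recovered cell mask
coincides with its true mask — at the default noise level the pipeline's
thresholds sit far from both intensity modes.

`examples/05_afm_and_qpcr.py` exercises the two assays:

```
noiseless curve generated at E = 5000 Pa -> fitted E = 5000.0000 Pa
with 5% force noise (20 curves): median fitted E = 5024 Pa

ddCt fold changes (true: ACTA2 x2, VCL x0.5):
 gene   ddct  fold
ACTA2 -1.118 2.170
  VCL  0.932 0.524
```

The noiseless Hertz fit is exact; with 5% force noise the median modulus
over 20 curves is within 0.5% of truth. The ΔΔCt folds recover the planted
2× up- and 2× down-regulation within replicate noise.

The remaining examples cover the phenotype-axis heat map (anchors land at
exactly 0 and 1), Shapley determinant ranking (a planted 3-SD feature ranks
first) and the spatial statistics (peripheral FA placement yields a 9.5 µm
mean FA–nucleus distance vs 6.1 µm perinuclear; a fiber texture planted at
30° is recovered at 29.5° with S = 1.000).

## Command line

A thin CLI mirrors the library: `fibromorph simulate / preprocess /
segment / measure / heatmap / spatial / rank / stats / fit-hertz / ddct /
run-all`. The whole pipeline on a simulated 4-condition study:

```bash
fibromorph run-all --outdir out --seed 7
```

writes per-condition scenes and morphometry CSVs, the feature matrix, the
normalized heat map (CSV + figure), FA–nucleus distances, orientations,
the Shapley ranking, group statistics and a provenance manifest. Re-running
with the same configuration and seed reproduces every CSV byte for byte.

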