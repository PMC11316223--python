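# Methods

This note documents the models, conventions and numerical choices behind
fibromorph, and what the synthetic validation does and does not establish.

## Coordinate and orientation conventions

Pixel coordinates are 0-based `(row, col)`; all physical quantities derive
from the isotropic pixel size (µm/px). Orientations are axial
(180°-periodic), in degrees, measured counterclockwise from the image
x-axis (columns increasing rightward, y up, i.e. against the row axis),
wrapped into `(-90°, 90°]` with the exact perpendicular mapping to +90°.
A micropattern at angle θ has its lines running along θ; 0° means
lines parallel to the x-axis. All circular statistics (means, SDs, the
order parameter S = |⟨e^{2iθ}⟩|) double the angles first, because cell and
fiber orientations have no head–tail distinction.

## Preprocessing

* **Maximum projection** collapses z-stacks per pixel; no deconvolution or
  flat-field correction is attempted.
* **Autocontrast** linearly rescales the `s/2` and `1 − s/2` intensity
  quantiles to [0, 1] with clipping; the default saturated fraction is
  s = 0.35% split evenly between tails, the convention of the common
  enhance-contrast tools. A constant image is passed through and flagged
  degenerate. The stretch is monotone, so segmentation thresholds commute
  with it.
* **White top-hat** (image minus opening with a flat disk) isolates FA
  puncta. The structuring element is a physical scale: the disk must be
  wider than the widest punctum or the opening retains FA interiors and
  the filter fragments them. The default radius is 1.25 µm converted to
  pixels (5 px at 0.25 µm/px); it is configurable.

## Segmentation

* **Otsu threshold**: explicit scan of the inter-class variance
  σ²_b(k) = ω₀ω₁(μ₀−μ₁)² over all histogram bin boundaries; the smallest
  maximizing boundary wins ties; a single-valued histogram is degenerate
  (empty foreground). Foreground is strictly above the threshold. Images
  are binned into 256 equal-width bins over their observed range.
* **Nuclei** (primary objects): Otsu foreground → hole filling →
  8-connected components → area filter (defaults 50–500 µm², covering
  normal fibroblast nuclei) → optional removal of border-touching objects
  (default on, so truncated shapes never enter the morphometry).
* **Cells** (secondary objects): the foreground is the Otsu-thresholded
  actin channel united with all nucleus pixels; each foreground pixel is
  assigned to the nucleus seed at the smallest geodesic distance *within*
  the foreground, computed by multi-source Dijkstra on the 8-connected
  pixel lattice with weights 1 (axial) and √2 (diagonal)
  (`scipy.sparse.csgraph.dijkstra`, `min_only`). This is deterministic and
  parameter-free, gives exactly one cell per nucleus, and each nucleus lies
  inside its own cell by construction. Foreground regions unreachable from
  any seed stay background.
* **FAs** (tertiary objects): Otsu computed over within-cell pixels only
  (the masking order matters: background pixels would otherwise dominate
  the histogram), components restricted to the cell union, minimum area
  0.4 µm², parent = the cell covering the majority of the punctum's
  pixels; puncta outside all cells are discarded.
* Interactive object editing is replaced by the deterministic filters
  above; externally corrected label maps can be injected by constructing
  `LabelMap` objects directly and calling `measure_objects` on them.

## Morphometry

Thirteen descriptors per object; the conventions are fixed because several
descriptors depend on them:

* **Moments**: second central moments of the pixel-centre point set;
  eccentricity e = √(1 − λ_min/λ_max); axis lengths 4√λ (a filled ellipse
  recovers its generating axes); orientation from the principal axis.
* **Perimeter**: chain-code length of the Moore-traced outer boundary,
  axial steps 1 and diagonal steps √2. This convention understates
  continuum perimeters slightly (a 10×10 px square walks 36 px), which is
  why it is stated explicitly; form factor 4πA/P² and compactness P²/4πA
  inherit it.
* **Feret diameters**: rotating calipers on the convex hull of the pixel
  *corner* points (using corners rather than centres makes a 10×10 square
  measure exactly 10 × 10√2 and keeps solidity ≤ 1 exactly).

The per-cell vector is a fixed, ordered 40-feature catalog: 13 cell + 13
nucleus descriptors, 13 FA aggregates (means and SDs of FA area,
perimeter, eccentricity and major axis; means of minor axis, aspect ratio,
solidity and form factor; total FA area) and the FA count. Cells without
FAs carry zero aggregates plus an explicit flag. FA SDs use the population
convention (ddof 0) so a single FA yields 0, not NaN.

**Two-point normalization**: for each feature, condition means are mapped
affinely so the control mean is 0 and the myofibroblast mean is 1; the map
is applied per (condition, day) group mean, using group means (not
medians) throughout. Features whose anchor gap is below a relative
tolerance of 1e-9 are flagged undefined rather than dropped, so the
feature grid keeps a stable shape.

## Determinant ranking

The classifier is a gradient-boosted tree ensemble
(`GradientBoostingClassifier`, 80 trees, depth 3, learning rate 0.1,
seeded), fitted one-vs-control per non-control condition on internally
standardized features; constant features are dropped with a warning.
Model quality is the 5-fold cross-validated accuracy; a comparison is
flagged unreliable when accuracy does not exceed the majority-class rate
by 1.645·√(p(1−p)/n) (a one-sided 95% margin), and the report carries the
flag so near-chance rankings are never silent.

Attributions are **exact interventional Shapley values** computed on the
tree structure. For a foreground sample x and a background sample z the
value function is v(S) = f(x_S, z_{S^c}) on the decision function
(log-odds, additive over trees). Each leaf is a product of per-feature
interval indicators; writing P for the path features satisfied only by x
and Q for those satisfied only by z (a feature satisfied by neither kills
the leaf; one satisfied by both is irrelevant), the leaf's Shapley
contribution is `value·(|P|−1)!|Q|!/(|P|+|Q|)!` to each feature in P and
the negative analogue to each feature in Q. Averaging over a background
set (default ≤ 64 training rows) gives attributions that satisfy local
accuracy exactly: base + Σφ = f(x), with base the mean model output over
the background. The engine is verified against full 2^n subset enumeration
(`exact_shapley`) to ~1e-15 on 8-feature models. Per-condition mean |φ| is
pooled across comparisons and ranked.

## Group statistics

One-way ANOVA from explicit between/within sums of squares (checked
against `scipy.stats.f_oneway`). Dunnett's many-to-one adjusted p-value
for comparison i is P(max_j |T_j| ≥ |t_i|) under the joint null of the
comparison statistics, which share the control mean and the pooled
variance; it is evaluated by seeded Monte Carlo (default 10⁵ draws of the
group means and the pooled χ² variance), giving reproducible results for
arbitrary group sizes. The estimate uses (count + 1)/(n + 1), so p never
reaches 0. Agreement with `scipy.stats.dunnett` is verified in the tests
to ~0.01.

## Auxiliary assays

* **Hertz (pyramid) fit**: F = tan α/(√2(1−ν²))·E·(δ−δ₀)² for δ > δ₀,
  with α the tip half-angle (default 35°), ν = 0.5 (incompressible
  cytoplasm), forces in nN and indentations in µm (conversion factor
  1e-3 from Pa·µm²). E enters linearly, so for each candidate contact
  point the optimal E ≥ 0 is closed-form; δ₀ is found by a coarse scan
  over the indentation grid plus bounded scalar refinement (xatol 1e-12).
  The contact point is fitted, not assumed, because real curves have an
  unknown contact. An all-zero curve returns E = 0 with a degenerate flag.
* **ΔΔCt**: ΔCt = Ct_target − Ct_reference per sample (GAPDH default);
  ΔΔCt = mean ΔCt(group) − mean ΔCt(control); fold = 2^−ΔΔCt. Control
  folds are exactly 1 by construction. No amplification-efficiency
  correction beyond the 2^−ΔΔCt model is applied.

## The synthetic-scene generator

The generator is the package's test harness: it emulates the *geometry*
of micropatterned fibroblast images well enough to validate segmentation
and measurement, with exact ground truth.

* All objects are superellipses; with the default exponent 2 they are
  exact ellipses, so analytic area πab, eccentricity √(1−(b/a)²), axes
  and centroid are recorded as truth. Rasterization is area-preserving:
  the N = round(πab/px²) pixels with the highest 4×4-supersampled coverage
  are selected, which keeps the rendered pixel count within rounding of
  the analytic area and the mask moments close to the generating
  parameters even for small puncta.
* Default study conditions: a 165 µm field at 0.15 µm/px with 10
  non-overlapping cells (length 40 ± 5 µm, width 13 ± 1.5 µm), one aligned
  nucleus each (13 ± 1.2 × 8 ± 0.8 µm), and 8 FAs per cell
  (4.4 ± 0.5 × 1.8 ± 0.15 µm, eccentricity ≈ 0.91, in the range reported
  for adherent fibroblasts). The pixel size was chosen so that binary
  masks of the smallest objects still carry their generating parameters:
  at 0.15 µm/px the worst-case FA major-axis and eccentricity deviations
  of the rendered masks are ≈1.9% and ≈0.009, within the recovery
  tolerances the tests enforce, with margin.
* FAs are split between a peripheral band (0.70–0.88 of the cell boundary
  radius) and a perinuclear annulus (1.0–1.3 of the nucleus boundary
  radius) with mixture weight `fa_radial_placement`, and cluster toward
  the cell's long-axis ends (axial von Mises, κ = 2), as adhesions do in
  elongated fibroblasts; this gives the distance statistic a tunable,
  cleanly separated true mean. Crowded or pattern-clipped cells fall back
  to progressively relaxed placement (uniform in the outline, then
  centred on actual mask pixels with ≥ 50% retention) so requested FA
  counts are always honoured; a cell that cannot host its adhesions at
  all raises a packing error rather than silently dropping objects.
* Orientations are sampled from a von Mises distribution on doubled
  angles centred on the pattern direction; concentration 0 is isotropic
  (the homogeneous control).
* On patterned scenes, cell bodies are clipped to the fibronectin stripes
  only when the gap exceeds a bridging width (default 15 µm; cells span
  smaller gaps, as observed at later culture times). Clipped cells must
  keep ≥ 45% of their body and be centred on a stripe, mimicking adherent
  placement; they are flagged, since their analytic shape truth no longer
  holds.
* Noise is signal-dependent Poisson (200 photons per intensity unit) plus
  additive Gaussian (SD 0.05 on a unit-intensity signal), giving
  foreground SNR ≈ 10 — a deliberately clean regime chosen so that the
  default segmentation recovers every object and parameter-recovery
  failures indicate algorithmic, not noise, problems.

What passing these tests does **not** show: robustness to uneven
illumination, out-of-focus light, touching or overlapping cells,
photobleaching, intensity-correlated textures or real PSF blur — none of
which the generator emulates. Results on real micrographs depend on those
factors; the synthetic validation establishes the correctness of the
algorithms, not the field-readiness of the default thresholds.

## Problem sizes and determinism

The test-suite and acceptance runs use desk-scale problems: the 1100² px
default scene, 700–760² px secondary scenes (4–6 cells), 20-seed
repetitions for the noisy-recovery and ranking studies, 10⁵ Monte Carlo
draws for Dunnett, and a 4-condition 768² px pipeline run executed twice
for byte-identical-output verification. Every stochastic component takes
an explicit seed (`numpy.random.default_rng`); the pipeline derives
per-condition seeds from the master seed, records them in the provenance
manifest, and writes CSVs with repr-precision floats so reruns are
byte-identical.

## Known limitations

* Single-plane analysis only; z-stacks are collapsed before segmentation.
* One nucleus per cell is assumed (multinucleated cells become one cell).
* The 40-feature catalog is a fixed, documented choice; intensity and
  texture features are out of scope.
* The Dunnett Monte Carlo assumes equal within-group variances (the
  classical pooled model).
* The Hertz model assumes a rigid pyramidal indenter on a semi-infinite
  elastic body; substrate effects and viscoelasticity are not modelled.
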