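# Methods

## Scope and model

`osteopore` quantifies cortical microporosity and trabecular
microarchitecture from calibrated micro-CT volumes of bone — 3-D grids of
tissue mineral density (TMD, mg HA/ccm) on an isotropic lattice, nominally
2 µm/voxel.  The analysis chain is:

1. **Region definition** (`roi`): user-drawn keyframe contours are
   propagated across intervening slices; a "middle third" of the cortical
   band can be cut between two anatomical anchor landmarks.
2. **Segmentation** (`segment`): Gaussian denoising (σ = 0.8 voxels, kernel
   truncated at ±1 voxel and renormalized, mirror boundaries) followed by a
   global bone threshold of 780 mg HA/ccm (inclusive, ≥).
3. **Microporosity** (`micropore`): pores are the inverted bone mask inside
   the cortical ROI; 26-connected components are classified by *physical*
   volume — < 100 µm³ noise, 100–1500 µm³ (closed interval) osteocyte
   lacunae, > 1500 µm³ vascular canals — and summarized as lacunar/vascular
   porosity (Lc.V/TV, Ca.V/TV, %), densities (N/mm³) and canal diameter
   (Ca.Dm, µm).
4. **Morphometry** (`morphometry`): BV/TV by voxel counting; Tb.Th and
   Tb.Sp by model-independent local thickness; Tb.N by the plate model
   (BV/TV)/Tb.Th.
5. **BMDD** (`bmdd`): two surface-voxel layers are peeled (6-connected
   erosion, so two layers remove exactly 4 µm at 2 µm voxels) before
   histogramming TMD; the curve is summarized by its weighted mean ("mean
   mineral density") and full width at half maximum ("mineral
   heterogeneity").
6. **2-D sections** (`bsem2d`): backscatter-style measurements — percent
   pore area by grey thresholding and area-classified components, lacuna
   major/minor axes by the second-moment ellipse, cortical thickness by the
   medial-axis distance ridge, canalicular width by sub-pixel threshold
   crossings of a line profile.
7. **Statistics** (`stats_report`): per-animal averaging, pooled-variance
   Student's t (two-tailed, α = 0.05), and min/quartile/max boxplot
   summaries.

## Design choices where the procedure was open

* **Contour interpolation.**  The commercial tool's "dynamic interpolation"
  is undocumented; we blend the signed distance fields of the bracketing
  rasterized polygons linearly per slice and threshold at zero, the standard
  shape-morphing construction.  It is exact for identical keyframes and
  varies area monotonically for nested convex outlines.  Rasterization uses
  the voxel-center even-odd rule.
* **Middle third.**  Parameterized by arc length along the band's *medial
  axis*: skeleton pixels get `t = d1/(d1+d2)` from geodesic distances to the
  two anchors, and each cortex voxel inherits its nearest skeleton pixel's
  `t`; `t ∈ [1/3, 2/3]` is kept.  Parameterizing voxels by their own
  point-to-point geodesics is biased toward the band middle (both distances
  share the voxel's radial offset), inflating the kept fraction by ~15 % on
  a thick annulus; the medial-axis form reduces to exact column thirds on a
  straight strip and angular thirds on an annulus.
* **Threshold convention.**  Inclusive (≥ 780), matching scanner lower-bound
  threshold semantics; boundary handling is mirror padding so edges are not
  darkened (which would bias edge porosity).  The filter runs on the full
  volume; the ROI is applied at thresholding.
* **Pore connectivity.**  26-connectivity for pores (bone is implicitly its
  6-connected dual); thin near-resolution links otherwise fragment pores.
  Volume class bounds compare physical µm³, not voxel counts, so they are
  resolution-independent (100 µm³ = 12.5 voxels at 2 µm).
* **Border pores.**  Pores touching the ROI boundary are kept but flagged
  `border_touching`; metrics can be computed with or without them
  (`include_border`).
* **Canal diameter and Tb.Th/Tb.Sp.**  Both use the largest-inscribed-sphere
  (Hildebrand–Rüegsegger) local thickness: Euclidean distance transform, then
  sphere painting from all voxels, largest radii first, with radii
  floor-quantized into ≤ 64 classes so painting is one distance transform
  per class.  Quantization only under-estimates, by ≤ 0.5 voxel in diameter
  at the defaults.  The summary is the volume-weighted mean.  Accuracy is
  ±~1 voxel, grid-placement dependent (a cylinder whose axis falls between
  voxel centers reads up to a voxel thin); the array border is treated as
  foreground-cutting, so structures should not touch it where thickness
  matters.
* **Tb.N estimator.**  The scanner's mid-axis method is unpublished; the
  plate-model (BV/TV)/Tb.Th is used and stated in the output so group
  comparisons remain internally consistent.
* **BMDD details.**  Peeling uses the 6-connected element per the 4 µm
  arithmetic above (26-connected erosion would remove more than two layers
  diagonally).  Histogram bins are centered on multiples of the bin width
  (default 5 mg HA/ccm — fine enough that FWHM interpolation error is far
  below reported group differences).  The histogram is built from the
  *unfiltered* calibrated densities on the peeled mask.  FWHM takes the
  global peak and the outermost half-max crossings adjacent to it, linearly
  interpolated; a single nonzero bin reports one bin width; a side that
  never falls below half maximum extends half a bin past the last center.
* **2-D pore classes.**  Only 3-D volume bounds exist; in 2-D, components
  below 4 µm² are noise and the lacuna/vascular split defaults to 80 µm²
  (a mid-range lacuna cross-section), both exposed as configuration.  Axis
  measurements use the moment ellipse (not Feret calipers), rotation- and
  translation-invariant to < 2 %.
* **Statistics.**  Equal-variance Student's t (not Welch) as specified by
  the protocol; quartiles by linear interpolation; no multiple-testing
  correction — a known limitation carried over deliberately.

## The synthetic phantom generator

The generator is the test substrate; its defaults are the study conditions
at 2 µm voxels:

| parameter | default | rationale |
| --- | --- | --- |
| voxel size | 2 µm | scan resolution |
| lacunar volumes | 100–600 µm³, log-uniform | reported span of 99 % of lacunae; distribution shape unreported, simplest documented choice |
| lacunar aspect | 2.9 : 1 prolate, random orientation | long/short axis ratio of healthy lacunae (≈ 9.5/3.3 µm) |
| canal radius | 15 µm | mid-range vascular canal (Ca.Dm ≈ 30 µm) |
| matrix density | N(1200, 60) mg HA/ccm, clipped ≥ 0 | cortical TMD well above the 780 threshold with realistic BMDD width |
| PSF blur | σ = 0.8 voxels | scanner-scale blur; applied before noise |
| noise | SD 25 mg HA/ccm | detector noise after blur |
| min pore gap | 2 voxels | keeps components separable at the resolution limit |

Cortical phantoms carve ellipsoidal lacunae and full-length cylindrical
canals out of a cortical band; trabecular phantoms are plate stacks
(BV/TV = t/(t+g) exactly when the stack is a whole number of periods) or
orthogonal rod lattices (BV/TV by inclusion–exclusion over one pitch cell;
Tb.Th = 2r).  Plates are phased half a gap into the stack so no plate lies
on the array face, where the distance transform would see no bounding
surface.  Every truth quantity (4πabc/3 ellipsoid volumes, πr²L canal
volumes, porosities, densities) is recorded analytically in `PhantomTruth`.
Geometry is fixed before blur, and blur/noise draw from the same seeded
generator, so a seed reproduces a phantom bit for bit.

What the phantom does **not** emulate: beam hardening, ring artefacts,
partial-volume calibration error, canalicular-scale porosity (below the
resolution), cement lines, and spatially correlated mineral gradients.
Passing recovery tests therefore demonstrates correctness of the
measurement chain on resolvable geometry, not scanner-physics robustness.

Parameter-recovery checks run with blur and noise disabled: with the fixed
780 mg HA/ccm threshold and σ ≈ 0.8 blur, the segmented boundary of a
~150 µm³ lacuna recedes ~0.4 voxel per face, pushing it below the 100 µm³
noise cutoff — the same resolution loss that makes 2 µm lacunar porosity
readings an order of magnitude below ≤ 1 µm studies.  The clean-geometry
phantoms isolate digitization error (± a few % on porosity, exact on
counts); the blur/noise defaults remain in force everywhere the realistic
conditions are the point (BMDD statistics, determinism checks).

## Numerical conventions

* Axis order (slice, row, column), 0-based, half-open crops; isotropic
  voxels only.
* Densities may be negative after calibration (air); bone thresholds are
  always positive.
* Metrics CSVs are written at 17 significant digits, so numeric round-trips
  are lossless and repeated runs of a seeded pipeline are byte-identical.
* Degenerate inputs raise `InputError`/`DimensionError` rather than
  returning sentinel values; the one deliberate sentinel is Ca.Dm = NaN
  when a specimen has no canals.

## Problem sizes

Self-tests use phantoms between 48³ and 400³ voxels (the 400³ recovery
phantom matches the ~50-lacuna density of the study ROI at 2 µm); the
acceptance script runs the same 400³ recovery plus default 200³ phantoms
for BMDD, morphometry and section rendering.

## Known limitations

* Local thickness carries the ±1 voxel grid-placement bias described above.
* Tb.N is a plate-model estimate, not the scanner's mid-axis method.
* The SDF contour interpolation is linear; a spline variant would differ
  slightly for widely spaced keyframes.
* 2-D lacuna measures ignore the out-of-plane orientation of ellipsoidal
  lacunae (a sectioning effect inherent to the 2-D approach).
* No multiple-testing correction in `stats_report`.
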