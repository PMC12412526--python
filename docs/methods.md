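# Methods

This note documents the models implemented in `vesselquant`, the defaults
and why they were chosen, what the synthetic data do and do not emulate,
and the numerical choices that affect results. It states no empirical
numbers beyond what the test suite and `scripts/acceptance.py` compute.

## Synthetic trunk vasculature (`synthvasc`)

The phantom emulates the en-face geometry of the larval zebrafish trunk:
a ventral axial vessel (dorsal aorta / caudal artery, drawn as one
centerline), a dorsal longitudinal anastomotic vessel, and `n_isv` evenly
spaced intersegmental vessels (ISVs) joining the two. The tumor-like
phenotype adds three effects, each with exact ground truth:

* **Axis bend** — both axial vessels share a smooth lateral displacement
  built from Gaussian-smoothed white noise (correlation length
  `bend_corr_len_px`, default 25 px), band-limited by subtracting a 4×
  more heavily smoothed copy and rescaled so the empirical standard
  deviation of the local heading angle equals `axis_bend_sigma_deg`.
  Displacement, not heading, is the generated quantity so the axis cannot
  random-walk out of frame; a hard cap (margin − max radius − 6 px) damps
  the rare realization whose heading variance sits in a single slow lobe.
* **ISV wiggle** — a transverse sinusoid (amplitude, period, random phase
  per vessel). Chains span the local heights of the bent axis and their
  terminal points are snapped onto the axial polylines, so every junction
  lies on both centerlines.
* **Hyperbranches** — straight bridges between adjacent ISVs with a mild
  sinusoidal bow (zero at the endpoints, amplitude half the ISV wiggle;
  new tumor vessels are not straight, and a perfectly straight digital
  chain would concentrate all its orientation samples in one histogram
  bin). Bridge heights come from a jittered lattice staggered by slot and
  gap parity, guaranteeing that two bridges sharing an ISV attach far
  enough apart for their junctions to stay resolvable after
  rasterization. Each bridge is perfused with probability
  `perfused_fraction`.

Arc and chord lengths are computed on the dense sub-pixel centerlines
(0.25 px steps); the sinusoid's arc length has no elementary closed form,
and dense polyline integration is accurate to well below the raster scale.
Rasterization sweeps a disk of the class radius along each centerline
(exact point-to-segment distances, no anti-aliasing, so pixel counts are
integer-testable); the perfused-only raster is pixelwise ≤ the all-vessel
raster by construction. Optional Gaussian blur and additive noise are
post-raster and default off.

`ground_truth_metrics` evaluates the five descriptors analytically:
windowed arc/chord ratios on centerlines split at junctions (mirroring
skeleton edges), tangent-angle statistics sampled at the same ±4 px scale
the skeleton estimator uses, exact junction counts, raster-exact density,
and radius-derived diameters.

## OCT simulation (`octsim`)

Repeat `r` of a BM-scan series carries per-pixel phase
`φ0 + r·(4π n v Δt / λ) + bulk_r + ε` on a static random baseline `φ0`,
with amplitude `intensity + amplitude noise`. Only the axial velocity
component is modeled (phase methods are axially sensitive); speckle is
replaced by per-pixel Gaussian phase/amplitude noise so every downstream
step can be checked against the closed form. Defaults mirror the imaging
context: λ = 800 nm, n = 1.33, interscan presets {30, 160, 330} ms.
Volumes are stored in HDF5 as `/complex_real`, `/complex_imag` shaped
(slow y, repeat r, depth z, fast x) with acquisition attributes.

A consequence of the 800 nm Doppler scale worth noting: at Δt = 160 ms a
mere 0.3 µm of axial motion is a full fringe, so any velocity above
~0.5 µm/s aliases — its wrapped phase is effectively arbitrary. "Slow flow
needs longer interscan times" is a sub-wrap statement; the simulated
phantoms therefore give severely impaired (hyperbranch) flow a sub-wrap
velocity (0.3 µm/s) so new tumor vessels appear dimmer than the
established network, and the interscan-time comparison uses the
contrast-to-background ratio, which is well-defined under aliasing.

## OCTA reconstruction (`octa`)

1. **Phase differences** between repeats `r` and `r+j`, wrapped to
   (−π, π]; `Δt_eff = j·Δt`. No spatial unwrapping is needed because only
   differences are processed.
2. **Bulk removal** per frame and A-scan: the intensity-weighted circular
   mean of Δφ over above-threshold pixels is subtracted and the result
   re-wrapped. Because adding a common-mode offset rotates the circular
   resultant by exactly that offset, the correction is exact for
   per-frame constant offsets regardless of the static-pixel fraction —
   this is the mechanism behind the bulk-invariance guarantee. A fully
   sub-threshold A-scan keeps offset 0 (logged).
3. **Aggregation**: mean |Δφ| across frame pairs by default (stable for
   the few repeats acquired in practice); phase variance is available and
   both are reported by the provenance. With one frame pair the variance
   path degrades to |Δφ|.
4. **Projection**: per depth slice, an optional orientation-selective
   smoothing (structure-tensor orientation, 5-px line kernels, 8
   quantized directions) and a 2-D median filter with disk radius 3 px;
   thresholding (absolute value, or the 95th percentile of a declared
   background region as the reproducible stand-in for an operator's
   manual threshold); maximum projection along depth; normalization to
   [0, 1].

The orientation-selective filter enhances vessel continuity for
visualization but its 8-bin orientation quantization smears curved
vessels slightly across orientations, broadening curvy masks
anisotropically. The bundled study therefore disables it for metric
extraction while it remains default-on in `denoise_and_project` for
display purposes.

## Fusion (`fusion`)

Registration is a coarse-to-fine grid search over rotation (and
optionally isotropic scale) with sub-pixel translation from phase
cross-correlation at each candidate, scored by normalized
cross-correlation; ties break toward the smaller transform, and a
correlation below 0.1 falls back to the identity with a warning. SSIM
uses the conventional defaults (Gaussian window σ = 1.5, 11×11 support,
k₁ = 0.01, k₂ = 0.03, dynamic range from the data); the local map can be
exported in the display convention where black = 1 and white = −1
(inverted hot colormap). Identical constant images are defined to score 1.

## Topology (`topology`)

* **Binarization**: multiscale Sato vesselness (σ ∈ {1, 2, 3}) → CLAHE →
  global Otsu, then removal of components < 12 px and filling of holes
  < 12 px (pinholes skeletonize into spurious junction pairs).
* **Skeleton graph**: 1-px topological skeleton; branch pixels within
  2 px (Chebyshev) merge into one junction node; spurs shorter than 3 px
  dangling from a junction are pruned, and junctions thereby reduced to
  degree 2 are spliced out. Edge `length_px` keeps the conventional
  1/√2 step accumulation.
* **Tortuosity**: windows of exactly 20 px of path slid at 1-px steps
  along each edge; per-window ratio = path / endpoint distance; edges
  shorter than the window contribute one whole-edge ratio (configurable).
  Chains are coordinate-smoothed (Gaussian, σ = 2) before measurement to
  suppress digital staircase inflation, and 3 px are trimmed at free edge
  ends where the rounded vessel cap leaves diagonal tips. A perfectly
  straight vessel scores exactly 1.0.
* **Orientation σ**: local orientations from a ±4 px central difference
  on chains smoothed with σ = 4 (heavier smoothing than for tortuosity —
  at 1° resolution a gently sloped digital vessel otherwise contributes
  almost all samples to the exactly-horizontal bin); angles folded to
  [−90°, 90°); 1° bins; a plain Gaussian fitted by least squares to the
  counts within ±45° of the dominant mode nearest the axis hint
  (default 0°, the anterior–posterior axis in image convention — the fit
  targets the axial-vessel peak, and the hint frame avoids the fold seam).
* **Density**: vessel-pixel fraction of the ROI, exact.
* **Diameter and bifurcation rate**: vessel area / skeleton length and
  junction count / (length / ROI area). Both use the smoothed-chain
  length rather than the raw √2 accumulation: the raw digital length
  overestimates tilted or curved chains by up to ~8 % (worst at 22.5°),
  which would systematically bias length-normalized metrics against
  curvier phenotypes. The bifurcation normalization convention is
  recorded in the output provenance; its absolute scale is arbitrary, so
  only ratios and directions are comparable.

## Study pipeline and statistics (`pipeline`, `stats`)

Per larva: sample phenotype parameters → generate phantom → rasterize GFP
(blur 1 px, noise σ 0.05) → simulate the BM volume (8 depth layers,
vessels in layers 3–5, tissue intensity 0.5, 4 repeats at Δt = 160 ms,
phase noise σ 0.15 rad, bulk offsets uniform ±0.5 rad per repeat and
position) → reconstruct (j = 1, intensity mask 0.2, mean |Δφ|, median
radius 3, auto threshold from a vessel-free background strip) →
translation-only co-registration and SSIM → five descriptors per channel
(automatic binarization) over a fixed trunk ROI.

Phenotype presets: healthy larvae use axis-bend σ 2.8°, wiggle 0.8 px
(period 50), no hyperbranches, full perfusion; tumor-phenotype larvae use
bend σ 7.5°, wiggle 2.5 px (period 45), 4–6 hyperbranches with perfusion
probability 0.4. The bend sigmas (2.8° healthy, 7.5° tumor) are set to group means
typical of the axis-angle metric in this assay, making them the
phenotype definition; vessel radii are matched
between groups (the diameter metric is deliberately non-discriminative)
with a 6 % per-larva radius jitter in both groups as biological
variability. Problem sizes (≈160×300 px en-face, 8 depth layers, 4
repeats, n = 20 per group) are chosen so the full study runs comfortably
on a single CPU.

Master-seed fan-out uses `SeedSequence([master, group_index, larva_index])`
so resizing one group never reshuffles another. Statistics follow the assay's
conventional protocol: Shapiro–Wilk first (a rejection warns and the analysis
proceeds), equal-variance two-sample t-tests (Welch via flag), labels
ns/*/**/*** at 0.05/0.01/0.001, no multiple-testing correction across the
five metrics (stated in the report footer).

## What the synthetic data do not show

The phantoms have no speckle, no transverse-flow decorrelation, no
depth-dependent signal roll-off, no breathing/peristaltic motion beyond
per-repeat bulk offsets, and a stylized two-dimensional geometry (no
subintestinal plexus, no head vasculature, no 3-D vessel crossings —
maximum projections of real volumes can overestimate bifurcations).
Passing recovery tests therefore demonstrates correctness of the
reconstruction and estimators under the stated noise model, not
performance on real animals; absolute metric values (especially the
bifurcation rate, whose scale is convention-dependent) are not comparable
to numbers measured on real animals, only their group directions are.

## Degenerate inputs and tie-breaks

Constant images are rejected by Otsu-based binarization; identical
constant images score SSIM 1 by definition. Zero-variance group pairs in
the t-test return p = 1 for equal means and p = 0 otherwise. A fully
masked A-scan gets bulk offset 0. Orientation fits with fewer than three
non-empty bins fall back to the weighted standard deviation
(bin-limited). Closed skeleton loops contribute windowed ratios but no
whole-edge ratio (a cycle has no endpoints). Registration ties break
toward the smaller transform magnitude.
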