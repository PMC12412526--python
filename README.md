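# vesselquant

Label-free vascular phenotyping for the larval zebrafish trunk: phase-based
OCT angiography (OCTA) reconstruction, fusion of OCTA flow maps with GFP
fluorescence structure maps, and topological vessel-network descriptors that
separate healthy from tumor-bearing (oncogenic RAS-expressing) vasculature.

The package is aimed at imaging scientists and quantitative biologists who
want a tested, reproducible implementation of this analysis chain — from
complex-valued repeated B-scans to group-level statistics — exercised end to
end on synthetic vasculature with exact geometric ground truth, since the
original animal imaging data are not publicly deposited.

## What it computes

**OCTA reconstruction.** Repeated B-scans at one slow-axis position
(BM-scans) separated by the interscan time Δt give wrapped phase differences

    Δφ(z, x) = arg( A_{r+j}(z, x) · A_r*(z, x) ) ,

where an axially moving scatterer contributes the Doppler phase
φ = 4π n v Δt_eff / λ (v axial velocity, n refractive index, λ center
wavelength, Δt_eff = j·Δt for pair separation j). Per A-scan, bulk motion is
removed by subtracting the intensity-weighted circular mean of Δφ;
sub-threshold intensity pixels are masked; the per-pixel flow contrast is
the mean |Δφ| across frame pairs (phase variance available as an
alternative). Depth slices are median-filtered (disk radius 3 px),
thresholded, and maximum-projected into an en-face map.

**Fusion.** OCTA (flow) and GFP (structure) en-face maps are co-registered
by a similarity transform maximizing normalized cross-correlation, merged
into a red(flow)/green(structure) composite, and compared with the
structural similarity index (SSIM; Gaussian window σ=1.5, 11×11, k₁=0.01,
k₂=0.03). A fully perfused network scores high; partially non-perfused
tumor vasculature scores low.

**Topology.** From a binary vessel mask over an ROI (automatic pipeline:
Sato vesselness → CLAHE → Otsu; or a provided mask) the skeleton graph
yields five descriptors: tortuosity (path/chord over overlapping 20-px
windows; 1.0 = straight), the σ of a Gaussian fitted to the vessel
orientation histogram (axis alignment), vessel density (vessel-pixel
fraction), mean vessel diameter (vessel area / skeleton length, in µm), and
bifurcations per ROI-normalized vessel length.

**Statistics.** Shapiro–Wilk normality check (warn, don't fail), then
two-sample t-tests with ns/*/**/*** labels at 0.05/0.01/0.001; no
multiple-testing correction across the five metrics.

**Synthetic ground truth.** `synthvasc` generates parametric trunk phantoms
(axial vessel pair, evenly spaced ISVs, optional hyperbranch bridges, axis
bend, sinusoidal ISV wiggle) with exact centerlines, junctions, and
analytic arc/chord ratios; `octsim` turns them into complex BM-scan volumes
with closed-form Doppler phases, bulk offsets, and noise, so every
reconstruction and every estimator can be validated by parameter recovery.

## Worked example

Run the bundled synthetic study (20 larvae per group; healthy "ras_minus"
vs tumor-phenotype "ras_plus"):

```python
from vesselquant import pipeline
report = pipeline.run_pipeline(None, out_dir="study_out")
print(report.summary_table.to_string(index=False))
```

prints (flow channel rows shown; mean with sd in parentheses):

```
channel                  metric        ras_minus         ras_plus
   flow              tortuosity    1.002 (0.000)    1.008 (0.002)
   flow   orientation_sigma_deg    2.766 (1.099)    6.479 (1.960)
   flow          vessel_density    0.139 (0.003)    0.151 (0.006)
   flow mean_vessel_diameter_um    7.165 (0.183)    7.238 (0.124)
   flow bifurcations_per_length 387.879 (68.184) 484.212 (66.377)
```

The tumor phenotype shows significantly higher tortuosity, axis-angle σ,
vessel density and bifurcation rate (all p < 0.001, equal-variance t-test,
n = 20/group), while mean vessel diameter does not differ (p = 0.15, the
generator uses matched radii) — the discriminative pattern this analysis is
designed to expose. The flow/structure SSIM is lower for the tumor group
(0.367 vs 0.376, p < 0.001), reflecting newly formed vessels that carry no
flow. `study_out/` receives per-larva metrics, group comparisons, the
summary table, and box plots.

The same steps are available from the shell:

```bash
vesselquant simulate --phenotype ras-plus --seed 3 --out-dir phantom
vesselquant simulate-oct --phenotype ras-plus --dt-ms 160 --seed 3 --out vol.h5
vesselquant reconstruct vol.h5 --pair-sep 1 --mask-threshold 0.2 --out flow.tiff
vesselquant fuse flow.tiff phantom/gfp.tiff --out merged.png --report report.json
vesselquant metrics flow.tiff --roi 12,148,8,290 --pixel-size-um 1.4 --out metrics.csv
vesselquant run --out-dir study_out
```

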