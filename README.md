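# renal-sabr-mri

Quantitative MRI and CT analysis pipeline for assessing the response of
primary renal cell carcinoma (RCC) to stereotactic ablative body
radiotherapy (SABR).

Morphological CT criteria such as RECIST respond slowly after SABR —
ablated tumours can keep their size for months while their physiology
changes — so functional MRI parameters are candidates for earlier response
biomarkers.  This package implements the complete analysis chain used to
evaluate that idea and validates every stage on digital phantoms with known
ground truth:

* **ADC analysis** — voxelwise mono-exponential fits to multi-b-value DWI
  (b = 50/400/800 s/mm²) and ROI histogram statistics (mean, median,
  skewness, Pearson kurtosis).
* **Semi-quantitative DCE** — a continuous piecewise-linear four-phase
  model (baseline, uptake, plateau, washout) fitted per voxel by exhaustive
  breakpoint search, yielding Tonset, IRE, ME, Twashout, IRW and a GD map
  classifying voxels as persistent / plateau / washout / non-enhancing.
* **Pharmacokinetic DCE** — SPGR signal-to-concentration conversion with
  fixed T1 (1142 ms kidney, 1664 ms blood, r1 = 2.8 L·mmol⁻¹·s⁻¹), an
  image-derived or population arterial input function, voxelwise extended
  Tofts fits,

      Ct(t) = Ktrans·∫₀ᵗ Cp(τ)·e^(−kep(t−τ)) dτ + vp·Cp(t),   kep = Ktrans/ve,

  and iAUGC60.
* **CT volumetry** — ellipsoid volumes V = π/6·AP·TR·CC, percentage change
  versus baseline, RECIST 1.1 categories (PR/SD/PD).
* **Response statistics** — per-patient change tables and Spearman rank
  correlations (exact permutation p for small n without ties, t
  approximation otherwise).
* **Synthetic data** — DCE/DWI phantoms whose voxels *earn* their
  enhancement-class labels from curve shape, plus longitudinal CT tables
  and full cohorts with injected monotone response trends.

## Worked example

CT volumetry and RECIST on the packaged 12-patient measurement table:

```bash
python analysis/01_volumetry_recist.py
```

prints

```
Per-patient volume change at last follow-up CT (%):
  patient  1:   -89.9  (PR)
  patient  2:   -88.1  (PR)
  patient  3:   -67.2  (PR)
  patient  4:   -66.2  (PR)
  patient  5:   -51.2  (SD)
  patient  6:   -34.8  (SD)
  patient  7:   +13.6  (SD)
  patient  8:   +24.3  (SD)
  patient  9:   +29.9  (SD)
  patient 10:   +37.9  (SD)
  patient 11:   +41.5  (SD)
  patient 12:   +91.8  (PD)

Range: -89.9% to 91.8%
RECIST: 4 PR, 7 SD, 1 PD
```

Each line is one patient's ellipsoid-volume change between baseline and
last follow-up CT and the response category implied by the longest-axis
change: four tumours shrank past the −30 % partial-response bar, one grew
past the +20 %/+5 mm progression bar, the rest are stable — even though
their volume changes span −51 % to +42 %, which is the motivation for
looking beyond size-based criteria.

The same library drives the phantom experiments:

```bash
python analysis/02_adc_validation.py        # exact + noisy ADC recovery
python analysis/03_dce_semiquant_validation.py  # GD-map confusion matrix
python analysis/04_dce_pk_validation.py     # Tofts parameter recovery
python analysis/05_cohort_correlation.py    # full pipeline on a 12-patient cohort
```

For example, `04` reports voxelwise recovery on a noiseless 720-voxel
phantom (median relative error ~1e-14 for Ktrans, ve, vp; with 1 %
concentration noise the median Ktrans error is ~2.8 %), and `05` recovers
an injected monotone washout-fraction/volume-change relation with
ρ = 0.99 (p = 1.3e-10) through the complete pipeline.

A `renal-sabr-mri` command exposes the same stages
(`simulate | adc | dce-semiquant | dce-pk | volumes | correlate | all`) over
a workspace of NIfTI volumes and CSV tables; see `renal-sabr-mri --help`.

## Layout

```
src/renal_sabr_mri/   library: adc, semiquant, pk, volumetrics, stats,
                      synthetic, cohort, aif, config, io, pipeline, cli
analysis/             numbered narrative drivers writing results/
tests/                pytest suite (unit, property and acceptance tests)
docs/methods.md       models, defaults, design decisions, limitations
```
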