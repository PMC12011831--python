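# octapipe

Quantification of retinal microvasculature on en-face OCTA flow images,
with the cohort statistics used to relate those measurements to diabetic
retinopathy (DR) severity, visual acuity and systemic blood biomarkers.

Optical coherence tomography angiography (OCTA) images blood flow in the
retina without dye.  In diabetes, capillary dropout around the optic disc
and macula precedes clinically visible retinopathy, so scalar summaries
of the capillary bed are candidate early biomarkers.  `octapipe` is aimed
at researchers who have en-face angiograms (or want fully synthetic
stand-ins) and need reproducible vessel metrics plus the standard
downstream analyses.

## What it computes

For each scan, inside a peripapillary annulus (outer ⌀ 1.375 mm, inner
⌀ 0.5 mm) or macular annulus (outer ⌀ 1.375 mm, inner ⌀ 0.75 mm) and
their quadrant/sector partitions, six vessel parameters of the capillary
bed (large vessels removed; ROI with |R| pixels, vessel/skeleton/
perimeter pixel counts A, S, P):

| metric | formula | meaning |
|---|---|---|
| VAD | A/\|R\| | vessel area density |
| VSD | S/\|R\| | skeleton (centerline) density |
| VDI | A/S | mean vessel caliber, px |
| VPI | P/\|R\| | perimeter density |
| VCI | (κP)²/(4πA), κ=π/2√2 | isoperimetric complexity/tortuosity |
| flux | mean flow over vessels | perfusion proxy |

Cohort analyses: Snellen→LogMAR conversion (−log₁₀(num/den)), visual-
acuity stability over follow-up (< 2 Snellen lines = stable),
control-standardized blood-panel z-scores, and OCT × OCTA Spearman
correlation matrices with per-panel Bonferroni correction and strength
labels (|ρ| < 0.3 weak, 0.3–0.7 moderate, ≥ 0.7 high).  Group
comparisons: Mann-Whitney U, Kruskal-Wallis H, chi-square, Welch's t
from summary statistics.

A synthetic-data module generates procedural vessel-network phantoms
with ground-truth masks (including a DR-grade dropout series) and
grade-conditional cohorts with a known latent coupling between RNFL
thickness and disc OCTA metrics, so the whole pipeline is testable
without patient data.  See `docs/methods.md` for the full model
description and design choices.

## Worked example

An end-to-end synthetic run — generate phantoms, quantify them, sample a
cohort (95 control + 218 DM eyes), and run the statistics battery:

```sh
octapipe demo --output-dir demo_out --seed 7
```

prints

```json
{
  "disc_max_abs_rho": 0.4805200070192955,
  "disc_n_cells": 150,
  "disc_n_significant": 148,
  "dm_pct_stable": 96.33,
  "dm_pct_worsened": 3.67,
  "lab_flagged_analytes": [],
  "lab_max_abs_z_grade_mean": 11.528138986683718,
  "macula_max_abs_rho": 0.24077863215242756,
  "macula_n_cells": 294,
  "macula_n_significant": 0,
  "n_dm_eyes": 218,
  "n_eyes": 313,
  "n_metric_rows": 15
}
```

Reading the numbers: the disc panel (RNFL quadrants × 30 OCTA
metric-region variables = 150 cells) shows strong coupling — the
synthetic cohort injects a latent vascular factor into both RNFL and
disc OCTA, and 148/150 cells stay significant after Bonferroni with
|ρ| up to 0.48 — while the macular panel, generated without coupling, has
none of its 294 cells significant.  96.33% of DM eyes kept stable visual
acuity (< 2 Snellen lines of change) over the simulated 4–7-year
follow-up, worsening being confined to grades DR3/DR4.  The largest
grade-mean lab z-score (11.5 control SDs) is the DR4 renal excursion.
`demo_out/` contains the tidy CSVs (vessel metrics per region, stability
and acuity-category tables, lab z-scores, correlation matrices) and the
rendered heatmaps.

Other subcommands: `octapipe simulate` (write phantoms + cohort CSV),
`octapipe quantify --image-dir ...` (TIFF/PNG images with JSON sidecars →
metrics CSV + QC report; scans with signal strength index ≤ 7 are
excluded), `octapipe analyze --cohort-csv ...` (statistics on an existing
cohort table, one row per eye).

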