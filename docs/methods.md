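# Methods

## Overview

`octapipe` quantifies retinal microvasculature on en-face OCTA flow images
and analyzes diabetic-retinopathy (DR) cohorts built from those metrics,
clinical grades, visual acuities, OCT thicknesses and blood panels.  The
pipeline has four stages: ROI geometry, vessel segmentation and metrics,
per-eye clinical encoding, and cohort statistics.  A synthetic-data module
generates vessel-network phantoms with known ground truth and
grade-conditional cohorts so every stage is testable without patient data.

## ROI geometry

En-face scans are square 3×3 mm² fields.  The peripapillary ROI is an
annulus of outer diameter 1.375 mm and inner diameter 0.5 mm centered on
the optic disc; the macular ROI uses outer 1.375 mm / inner 0.75 mm
centered on the foveal avascular zone.  Scans are treated as centered on
the target structure (an explicit center in mm is accepted); automatic
disc/FAZ localization is out of scope.

Rasterization uses pixel centers and the half-open interval
`inner_radius ≤ d < outer_radius`, which makes concentric rings and
adjacent sectors exactly disjoint.  Row 0 is anatomically superior;
angles are measured with 90° at image top.

Sector conventions (chosen here; the quadrant names are standard RNFL
practice but no source fixes the boundary angles):

* Disc quadrants on the 45° diagonals: S = [45°, 135°), I = [225°, 315°),
  with nasal/temporal filling the horizontal quadrants according to eye
  laterality (for OD, nasal is displayed on image-left).
* Macular six-sector scheme: superior and inferior hemifields each split
  into three 60° sectors (S and I vertical, SN/ST and IN/IT flanking),
  again mirrored between OD and OS.

The annulus mask area converges to the analytic annulus area as
resolution grows (relative error ≈0.24% at 128 px, ≈0.06% at 512 px on
the disc annulus).

## Vessel segmentation

1. **Quality control.** Only scans with device signal strength index
   strictly above 7 are quantified; SSI = 7 fails.
2. **Enhancement.** Intensity-weighted multiscale Hessian vesselness:
   a Frangi response `V` at scales {1, 2, 3} px (capillary calibers at
   ~10 µm/px), normalized to [0, 1], modulates the flow image as
   `E = I·((1−w) + w·V)` with weight `w = 0.5`.  Pure vesselness
   (`w = 1`) collapses at junctions and inside vessels wider than the
   filter scales, which destroys mask accuracy on networks; keeping the
   flow signal where tubularity is confirmed preserves junctions while
   still attenuating smooth background.  Constant images map to a
   constant (zero-vesselness) output, and the operator commutes with 90°
   rotations.
3. **Thresholding.** Global Otsu on the enhanced image by default; a
   fixed level is available (`pixel ≥ level`).  Raising the level can
   only shrink the mask.
4. **Large-vessel removal.** Capillary-bed metrics exclude large vessels.
   Vessel width is measured by the Euclidean distance transform: pixels
   with medial depth ≥ cutoff/2 (default cutoff 6 px ≈ 60 µm) form
   large-vessel cores, restored to full width by a disc dilation
   constrained to the mask.  Crossings of thin vessels do not qualify,
   since their medial depth stays below the cutoff.  The capillary and
   large-vessel masks are disjoint and union to the input.  Removal is
   applied to disc and macula alike.
5. **Skeleton and perimeter.** Topology-preserving morphological
   thinning yields one-pixel centerlines (a cleanup pass resolves rare
   two-pixel-thick spots without changing the 8-connected component
   count).  The perimeter map marks vessel pixels with at least one
   4-neighbor outside the mask.

## Vessel parameters

Within an ROI of `|R|` pixels, with vessel/skeleton/perimeter counts
`A`, `S`, `P`:

* VAD = A/|R| — vessel area density
* VSD = S/|R| — vessel skeleton density
* VDI = A/S — vessel diameter index (mean caliber, px); undefined when
  S = 0
* VPI = P/|R| — vessel perimeter index
* VCI = (κP)²/(4πA) — vessel complexity index, the isoperimetric
  quotient, with κ = π/(2√2) ≈ 1.111 the mean contour length per
  4-boundary pixel of an isotropically oriented smooth curve.  Without
  this calibration the raw pixel count underestimates contour length by
  ≈10%, putting an ideal disc at VCI ≈ 0.79 instead of ≈ 1; with it a
  radius-20 px disc measures ≈ 0.98.  VPI deliberately keeps the raw
  count, matching its definition as a pixel fraction.
* flux = mean normalized flow intensity over capillary pixels in the ROI,
  a perfusion proxy (per-pixel flow is the only observable in an en-face
  image; whether the device's flux index weights differently is unknown
  and documented as such).

Because skeleton and perimeter are subsets of the vessel mask,
VSD ≤ VAD and VPI ≤ VAD always hold.  A vessel-free ROI reports zero
densities with VDI/VCI flagged undefined.

## Clinical encoding

* LogMAR = −log₁₀(Snellen numerator/denominator); 20/20 → 0.0,
  20/200 → 1.0.  Low-vision categories are imputed at conventional
  values (CF 1.9, HM 2.3, LP 2.7, NLP 3.0) and flagged.
* The default Snellen chart runs 20/10 … 20/400 then CF/HM/LP/NLP; it is
  configurable.  Acuities off the chart map to the nearest line (by
  LogMAR) with a warning flag.
* Stability over follow-up: a change of fewer than two chart lines is
  stable; a drop of two or more lines is worsened; a gain of two or more
  is improved.  The classifier is antisymmetric under swapping baseline
  and follow-up.
* Acuity categories (configurable): 20/20–20/30, 20/40–20/60,
  20/70–20/100, 20/200 or worse.
* Blood panels (24 analytes) standardize per analyte against the control
  group: z = (x − mean_ctrl)/sd_ctrl, so control z-scores are standard by
  construction; zero-spread analytes are flagged and excluded from the
  heatmap.

## Statistics

Two-tailed Mann-Whitney U (exact enumeration when total n ≤ 12 and the
pooled sample is tie-free; otherwise the tie-corrected normal
approximation with continuity correction — the correction keeps the
approximation within 0.02 of the exact p at n = 6+6, where the
uncorrected version deviates by up to 0.07), Kruskal-Wallis H with
chi-square reference, Pearson chi-square without continuity correction,
Welch's t from summary statistics with Welch–Satterthwaite df, and
Spearman rank correlation with mid-ranks and the t approximation on
n − 2 df.

OCT × OCTA correlation matrices cross thickness variables (RNFL
quadrants, GCC sectors) with vessel metrics per region on
pairwise-complete observations; eyes are treated as independent
observations.  Bonferroni family = all cells of one panel by default
(disc and macula corrected separately), with a global-family option.
Strength labels by |ρ|: [0, 0.3) weak, [0.3, 0.7) moderate, [0.7, 1]
high; boundary values go to the upper category.  Under a global null the
family-wise error after Bonferroni stays at or below α within binomial
tolerance (the Spearman t-approximation is mildly anti-conservative at
small n, so realized rates can sit at α).

## Synthetic data

**Phantoms.**  Large trunks enter from the superior edge and cross the
field (width 10 px); capillary branches are random walks with direction
persistence (width 2 px, secondary branching), added until a target
capillary density is met (default 0.25; > 0.9 is rejected as
unsatisfiable).  Flow intensities: background 0.10, capillaries
≈ 0.55, trunks ≈ 0.85, optional Gaussian speckle (default sd 0.05),
clipped to [0, 1].  Ground-truth vessel/large-vessel masks are returned
noise-free.  Grade series emulate progressive microvascular dropout by
nested deletion of capillary branches, so VAD is monotone nonincreasing
by construction and VCI declines with it.

What the phantoms do not emulate: projection artifacts, motion stripes,
vessel-caliber tapering, foveal avascular zone morphology, and
device-specific speckle statistics.  Passing the recovery suite shows
the geometry pipeline is correct on controlled networks, not that
segmentation accuracy transfers to clinical images.

**Cohorts.**  Per-eye records sample grade-conditional Gaussians using
the published per-grade means/sds for the 24 lab analytes and the
RNFL/GCC thicknesses as parameters; controls reuse the DR0 OCT
distributions (no control column is published).  Values are truncated
(clipped) at physiologic floors (0; EGFR ≥ 5), which biases the mean
upward only where the floor is close — materially only for DR4
creatinine (2.54 ± 2.54, bias ≈ +0.7).  Default group sizes mirror the
study scale (95 control eyes, 218 DM eyes split 80/52/44/12/30 across
DR0–DR4; the small DR3 group is consistent with the near-zero DR3
spreads in the published labs).

A per-eye latent vascular factor with loading λ (default 0.632) enters
both RNFL thickness and every disc OCTA metric, giving Pearson r = λ²
(≈ 0.4) and Spearman ρ = (6/π)·asin(r/2) between any coupled pair; GCC
and macular OCTA are sampled independently, reproducing the qualitative
disc-coupled / macula-uncoupled structure.  Cr, BUN and EGFR share a
renal latent factor (loading 0.6, EGFR negative) — an explicit modeling
choice reflecting renal physiology, not a published estimate.  OCTA
metric levels (VAD 0.42, VSD 0.16, VDI 2.6, VPI 0.30, VCI 1.9, flux
0.45, declining 4% per grade, 10% relative sd) are realistic synthetic
defaults, not published summaries.

Baseline acuity starts at 20/20 plus a geometric number of chart lines
down with a grade-dependent step probability (controls ≈ 90% within
20/20–20/30).  Follow-up worsens by ≥ 2 lines with per-grade
probabilities (default 0 for Ctrl/DR0–DR2, 0.2 for DR3, 0.3 for DR4,
confining worsening to severe grades as observed); otherwise it jitters
by at most one line.  Visual-acuity transitions act on chart lines, so
the two-line classifier is exercised natively.

## Numerical and design notes

* All generators take a single integer seed (`numpy` `default_rng`);
  pipeline stages derive seeds deterministically from the run seed via
  CRC-tagged `SeedSequence`.
* Problem sizes in the test and acceptance suites: 300 px phantoms for
  segmentation checks, 512 px bar grids for metric recovery, 2,000
  replicates for the Kruskal-Wallis null, 1,000 simulations for the
  family-wise-error check, n = 500 × 10 seeds for coupling recovery —
  sizes at which sampling error is small relative to the tolerances
  while the whole suite stays fast.
* Degenerate inputs: empty ROI is an error; vessel-free ROI flags
  VDI/VCI undefined; constant samples are rejected for Spearman;
  zero-spread control analytes are flagged out of standardization;
  annuli clipped by the field set a clipping flag, annuli fully outside
  raise.
* The disc annulus outer diameter of 1.375 mm is implemented exactly as
  specified though it is small relative to a typical disc; all diameters
  are configurable.

## Known limitations

* Segmentation accuracy is validated on procedural phantoms only.
* The flux index is a mean-intensity proxy; device flux indices may
  weight flow differently.
* Eyes are treated as independent; inter-eye correlation within subject
  is not modeled (an option to average fellow eyes exists at analysis
  level by pre-aggregating the cohort table).
* True inter-analyte correlations are unknown; only the renal block is
  coupled.
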