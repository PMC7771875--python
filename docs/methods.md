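# Methods

This note documents the models, conventions, and design choices behind
`aptwq`, in the order data flows through the package: Z-spectrum
quantification, synthetic data, ROI extraction, cohort assembly, and the
statistical battery.

## APTw quantification

### Signal model and conventions

Saturation at an offset δ (ppm relative to water, positive downfield)
attenuates the water signal; normalizing by the unsaturated reference S0
gives the Z-spectrum Z(δ) = S(δ)/S0 ∈ [0, 1]. Amide protons of mobile
proteins resonate near +3.5 ppm, so the APTw score is the asymmetry of the
Z-spectrum about the water line, averaged over a window centred on the
amide offset:

    APTw = ( ∫ Z(δ) dδ over [−c−h, −c+h] − ∫ Z(δ) dδ over [c−h, c+h] ) / 2h

with c = 3.5 ppm and h = 0.4 ppm by default (a 0.8-ppm window). The result
is a dimensionless fraction of S0; multiply by 100 for percent. Offsets in
Hz convert to ppm with the proton gyromagnetic ratio, 42.576 MHz/T.

The default acquisition protocol is a 3 T clinical CEST scheme: B1 = 2 µT,
21 offsets evenly spaced over ±610 Hz (±4.776 ppm), a train of five 100 ms
pulses with 61 ms gaps, and an S0 volume acquired with −150 ppm
off-resonant pre-saturation. Pulse-train spin dynamics are out of scope:
the engine consumes measured (or generated) intensities; it does not solve
Bloch-McConnell equations.

Two S0 semantics exist in practice: an ideally unsaturated reference, or
the −150 ppm acquisition that still carries a trace of semisolid
saturation. The generator supports both (`s0_mode="ideal"` /
`"presaturated"`); the default is `ideal`, and no macromolecular-background
subtraction is applied beyond what the asymmetry itself performs.

### Interpolation and quadrature

The acquired grid (~0.48 ppm spacing) holds at most two samples per
0.8-ppm window, so a direct sum over acquired points would depend on grid
phase. The engine instead interpolates the sampled spectrum with a cubic
spline, evaluates it on a 0.01-ppm fine grid over each window, integrates
by the trapezoid rule, and divides by the window width — a window average
in units of S0. The negative-window fine grid is the exact mirror of the
positive one, so spectra symmetric about 0 ppm give an asymmetry of
exactly zero (to ~1e-15), and mirroring a spectrum negates the result
exactly. For spectra linear across the window the trapezoid equals the
midpoint value exactly.

### B0 correction

Field inhomogeneity shifts each voxel's spectrum; the correction
re-centres it using the bottom of the Z-spectrum (the direct-saturation
dip). The dip is first located by argmin of the spline on the 0.01-ppm
fine grid within ±1.5 ppm; a minimum on the search boundary (e.g. a
monotone spectrum) raises an uncorrectable-spectrum error. The argmin of a
spline through a 0.48-ppm grid, however, carries a sampling-phase-dependent
bias of up to ±0.02 ppm, which at the slope of the amide line translates
into ~0.1 percentage-point APTw errors. The centre estimate δ0 is therefore
refined as the point of **maximum flank symmetry**: among candidate centres
within ±0.3 ppm of the argmin, the one minimizing the summed squared
difference between the two flanks of the dip (out to 1.2 ppm, on the same
fine grid). This estimator's residual bias is phase-independent (~0.002
ppm) and cancels between spectra, restoring shift invariance: APTw after
correcting a δ-shifted spectrum agrees with the unshifted value to within
0.05 percentage points for |δ| ≤ 0.5 ppm (worst case measured: 0.031 pp).
The corrected spectrum is the spline resampled at the nominal offsets
shifted by +δ0, with `b0_shift_ppm = δ0` recorded.

### Stored-intensity codec

Scanner maps store APTw as 12-bit integers: code = round(aptw·20000) +
2048, i.e. aptw = (C − 2048)/20000 with scale factor 10. Code 2048 is
zero; one code step is 0.005 percentage points; the representable range is
[−10.24 %, +10.235 %]. Encoding clamps out-of-range values with a
saturation warning; the decode→encode round trip is lossless over all 4096
codes. Integer NIfTI exports are flagged in the header description field.

### Voxelwise maps

`compute_aptw_map` runs normalize → B0-correct → window asymmetry per
voxel of a 4-D offset stack. Voxels with non-positive S0 or an
uncorrectable spectrum become NaN and are tallied in a QC summary; missing
voxels make an ROI centre inadmissible rather than being skipped silently.
Maps are indexed 0-based row-major and carry voxel size but only an
identity world affine — the package works on synthetic, voxel-aligned data.

## Synthetic data

### Multi-pool Z-spectra

Each tissue class is a sum of Lorentzian saturation lines on the
normalized scale: direct water saturation at 0 ppm, a broad (50 ppm)
semisolid MT pool centred at −2.4 ppm, a relayed NOE line at −3.5 ppm, and
the amide line at +3.5 ppm. A Lorentzian line model is used instead of
Bloch-McConnell simulation deliberately: the package's claims concern the
asymmetry statistic and the downstream analysis, not saturation physics.

Line widths reflect saturation broadening at B1 = 2 µT (γB1 ≈ 85 Hz ≈ 0.7
ppm at 3 T), which dominates the effective width of the exchanging pools:
amide 2.0 ppm, NOE 3.5 ppm, water 2.0–2.2 ppm (1.2 ppm for the long-T2
fluid class). Narrower lines would be under-sampled by the 21-offset grid
and are not what a 2 µT experiment produces.

Five classes ship: NAWM (normal-appearing white matter), LGG, HGG, MET,
and CSF-like fluid. The amide amplitude of each class is not a hand-picked
constant: it is **calibrated by root-finding through the actual
quantification pipeline** so that the engine recovers the class's nominal
APTw — 0 % for NAWM and CSF (the asymmetry is referenced to zero in normal
tissue), 1.49 % for LGG, 2.60 % for HGG, 2.49 % for MET, the cohort group
averages the generator is meant to emulate. This closes the
generator/engine loop: parameter recovery is exact by construction at the
default protocol and is property-tested at ±0.2 pp. Amide amplitudes are
ordered NAWM < LGG < HGG, and APTw is strictly increasing in the amide
amplitude.

Noise is Gaussian on the normalized signal (default sd 0.005 of S0, the
contrast-to-noise regime of a short saturation train at 3 T); a Rician
option exists for magnitude data, and at these SNRs the Gaussian model is
adequate and analytically checkable. All randomness flows from one seeded
generator; identical parameters and seed give bit-identical outputs.

### Lesion phantoms

A phantom spec defines a voxel grid (default 2×2×4 mm voxels), a
background class, spherical lesions (centre in voxel indices, radius in
millimetres; in-plane containment required, through-plane clipping by thin
slabs allowed), an optional concentric necrotic core per lesion (rendered
as fluid and marked in the exclusion mask), a smooth polynomial B0 offset
map, and a noise level. Overlapping lesions are rejected. The builder
returns the 4-D offset stack, S0 volume, lesion and exclusion masks, and a
truth table with each lesion's class and expected APTw. What the phantoms
do **not** model: anatomy, partial-volume voxels, contrast enhancement,
motion — so passing image-level tests demonstrates correctness of the
quantification chain, not robustness to those real-data effects.

### Simulated cohorts

The cohort simulator draws per-subject (mean, max, min) APTw triples from
a correlated trivariate normal per group, rejection-sampled until ordered
(min ≤ mean ≤ max) — effectively a truncated normal on the ordered region.
Defaults are the reference cohort's group statistics (HGG 2.60±0.97, LGG
1.49±0.50 for the mean, analogously for max and min) with a common
within-subject correlation of 0.8, reflecting how concordant the three
statistics are in practice (the value is config-exposed). At these effect
sizes the two-group comparison of the mean rejects at α = .05 in well over
80 % of simulated cohorts of 16 + 6.

### Reference cohort

A 26-subject glioma/metastasis series ships as versioned CSV inside the
package: histology and WHO grade, IDH/MGMT status, the initial radiological
diagnosis, and per-subject APTw mean/max/min in percent. Four subjects are
annotated for exclusion — two LGG with radiological progression after
histological sampling, and the two metastases (a group of two is below the
n ≥ 4 floor for statistical analysis) — leaving the 22-subject analysis
set of 16 HGG vs 6 LGG. The within-subject range is defined as max − min
and always derived on load, never stored. One histology note: the running
description of the cohort identifies subject 23 as the single anaplastic
astrocytoma (grade 3); the fixture records that, and the subject is in the
HGG group either way.

## ROI extraction

The clinical reading places one circular ROI of 10 pixels at the location
of highest APTw signal in viable lesional tissue. "Size of 10 pixels" is
interpreted as a 10-member digital disc — the 10 in-plane voxels nearest
the centre, ties broken by (row, col) — rather than a 10-pixel diameter;
the member count is config-exposed. The search is 2-D per slice (ROIs live
on slices), exhaustive over all admissible centres, maximizing the disc
mean; ties break toward the lowest slice, then row, then column, making
placement fully deterministic. A centre is admissible only if every member
voxel is inside the image and lesion mask, outside the exclusion mask
(hemorrhagic/cystic/necrotic tissue is an *input* mask, not detected), and
finite-valued. This automated maximal-mean search is a reproducible
surrogate for manual radiologist placement and is labelled as such in
outputs. Statistics (mean, max, min, range = max − min) are reported in
percent; a whole-lesion single-slice variant aggregates all admissible
lesion voxels on one slice.

## Grade classification

Threshold rules call HGG when a statistic strictly exceeds a cutoff
(rules are quoted as "> cutoff", so boundary equality is LGG; the
convention is config-exposed). Grade-3 tumours group with HGG. Metastases
pass through rules for reporting but never enter sensitivity (correct
HGG / all HGG) or specificity (correct LGG / all LGG); an absent group
leaves its rate missing, never zero.

The combined model is a maximum-likelihood logistic regression of grade on
mean, max, and range, fitted by Newton-Raphson (log-likelihood tolerance
1e-8, ≤25 iterations, step halving). Singular designs raise; complete
separation is detected (diverging linear predictors, or all fitted
probabilities collapsed onto 0/1) and flagged with a warning, never
silently.

One operating-point caveat, documented rather than hidden: the table of
published operating characteristics pairs the combined model with a
probabilistic cutoff of 0.38, but on the reference cohort the fitted
probabilities give four errors at 0.38 (subjects 3, 7, 11, 17 — subject 11
sits at p ≈ 0.41), whereas the model's published error set {3, 17, 7} and
its 93.8 %/100 % sensitivity/specificity correspond to the conventional
0.5 classification threshold (sens/spec hold for any threshold in
(0.59, 0.65), the Youden point of the fitted probabilities). The package
keeps 0.38 as the default probabilistic cutoff for compatibility, reports
misclassifications at both 0.38 and 0.5 in every summary, and the
acceptance test pins the error set at 0.5.

## Statistical battery

* **Mann-Whitney U** — midranks for ties; U reported from the smaller
  rank-sum side (the clinical-package convention). The exact two-sided p
  comes from the permutation null: a dynamic-programming rank-sum
  distribution when the pooled data are tie-free, full enumeration over
  assignments otherwise, whenever n1·n2 ≤ 1e5. The asymptotic p is the
  tie-corrected normal approximation, by default without continuity
  correction (this is what reproduces published two-group p-values from
  SPSS-era analyses); `continuity=True` applies the 0.5 correction, which
  tracks the exact p within ~0.01 at n ≥ 8, versus ~0.05 without. The
  exact test's empirical size at α = .05 and n = (16, 6) is 0.049.
* **ROC** — empirical curve over all distinct thresholds ("positive if
  score > t"); AUC via the rank (concordance) form, which gives half
  credit to ties and equals 1 − U/(n1·n2) on tie-free data. The operating
  point maximizes Youden's J; the reported cutoff is the midpoint between
  the adjacent distinct observed scores (this midpoint convention is what
  reproduces published cutoffs such as 1.90/2.48/0.91 from the reference
  cohort), with J-ties broken toward higher specificity. The AUC CI uses
  DeLong's variance; other software may use different SEs, so CIs are
  reported but never asserted against published values.
* **Logistic diagnostics** — omnibus = likelihood-ratio test against the
  intercept-only null; Nagelkerke R² = Cox-Snell divided by its maximum
  attainable value; Hosmer-Lemeshow over deciles of fitted probability
  with ties kept together (the group count shrinks with a warning when
  fitted probabilities tie; the p-value is reported only — it is
  binning-sensitive and not a comparison target).
* **Shapiro-Wilk** — Royston's algorithm via scipy, guarded for
  3 ≤ n ≤ 5000 and non-constant input; used as a descriptive normality
  screen motivating the nonparametric comparisons.
* **Molecular strata** — descriptive n/mean/sd of an APTw statistic by
  MGMT or IDH status; unknown-status subjects are dropped with the count
  reported, strata under n = 4 are flagged insufficient for testing, and
  empty strata report missing values, never zero. No multiplicity
  correction is applied anywhere (none is part of the reproduced
  analysis).

## Pipeline, rounding, determinism

`run_pipeline` ties the stages together from a JSON `RunConfig` (unknown
keys rejected; serialization round-trips): cohort → exclusions →
descriptives, U tests, ROC, combined model, threshold audits, subgroup
means → CSV/JSON artifacts plus a manifest with SHA-256 content hashes.
Runs are deterministic given the seed; two runs of the same config produce
identical manifests. Rendered tables use display rounding only (group
averages 2 dp, AUC 3 dp, sensitivity/specificity 1 dp) with decimal
half-away-from-zero rounding — a mean of two-decimal inputs like 2.595
prints as 2.60 — while JSON artifacts always carry full precision.

## Problem sizes in the shipped tests

The test suite exercises phantoms up to 24×24×3 voxels (the ROI search is
verified against brute-force enumeration there and is equivalent at any
size by construction), 200-replicate noise Monte-Carlo, 300 simulated
cohorts for the power check, and 10,000 null simulations for the exact
test's size; the full suite runs in well under a minute on one CPU.

## Known limitations

* The Lorentzian line model omits exchange dynamics, B1 inhomogeneity,
  and MT-pool lineshape asymmetries beyond a shifted Lorentzian; phantom
  realism is anchored only through the class-level APTw calibration.
* The symmetry-based B0 refinement assumes a locally symmetric
  direct-saturation dip; strongly asymmetric pathology at |δ| < 1.2 ppm
  would bias it (as it would bias any bottom-of-spectrum method).
* Subject-level statistics reproduce a small single-centre cohort; the
  classifier cutoffs are descriptive of that cohort, not validated
  decision thresholds.
* DICOM ingestion is out of scope; volumes are NIfTI-1 and tables CSV.
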