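# aptwq

Amide-proton-transfer-weighted (APTw) MRI quantification and glioma
grading, as a tested, end-to-end pipeline.

APTw imaging is a chemical exchange saturation transfer (CEST) technique:
selective saturation of amide protons of mobile proteins (~+3.5 ppm
downfield of water) attenuates the water signal through chemical exchange,
so tumours with elevated mobile-protein content light up. Because
high-grade gliomas (HGG, WHO grade 3–4) carry more mobile protein than
low-grade gliomas (LGG, grade 2), the APTw signal can grade a lesion
non-invasively before surgery — a question that matters clinically because
contrast-enhanced MRI alone misgrades a substantial fraction of gliomas.
This package is for imaging scientists and biostatisticians who want that
analysis chain reproducible from raw saturation images to the grading
statistics.

The quantity at the core is the Z-spectrum asymmetry integral. With
Z(δ) = S(δ)/S₀ the normalized water signal at saturation offset δ (ppm,
positive downfield),

    APTw = MTRasym(3.5 ± 0.4 ppm)
         = ( ∫₋₃.₉^₋₃.₁ Z dδ − ∫₊₃.₁^₊₃.₉ Z dδ ) / 0.8 ppm

computed per voxel after B0 correction (re-centring each spectrum on the
bottom of its direct-saturation dip), and stored by the scanner codec
APTw = (C − 2048)/20000 for 12-bit intensities C. Subject-level statistics
(mean, max, min, range of the lesion ROI, in % of S₀) then feed a
two-group battery: Mann-Whitney U with exact permutation p-values,
empirical ROC with Youden-midpoint cutoffs, and a combined logistic model
P(HGG) = σ(β₀ + β₁·mean + β₂·max + β₃·range) with Nagelkerke R²,
likelihood-ratio omnibus, and Hosmer-Lemeshow diagnostics.

The package covers:

* `aptwq.zspectrum` / `aptwq.aptmap` — normalization, B0 correction
  (spline fine grid + maximum-symmetry dip centring), the MTRasym window
  integral, the integer codec, voxelwise maps with QC, NIfTI I/O.
* `aptwq.phantom` / `aptwq.cohort` — multi-pool Lorentzian Z-spectrum
  generator (water/MT/NOE/amide), digital lesion phantoms with B0 fields
  and necrotic cores, a seeded cohort simulator, and a packaged
  26-subject reference cohort (16 HGG / 6 LGG after exclusions).
* `aptwq.roi` — deterministic 10-pixel digital-disc ROI search for the
  maximal signal, plus a whole-lesion single-slice variant.
* `aptwq.grading` / `aptwq.stats` — exclusion rules, threshold and
  logistic grade classifiers, and the statistical battery.
* `aptwq.cli` — `aptwq` command with `simulate-phantom`, `compute-aptw`,
  `roi-stats`, `simulate-cohort`, `cohort-stats`, `classify`, `report`.

## Worked example

```python
from aptwq import (load_table1_fixture, apply_exclusions, ThresholdRule,
                   classify_cohort, fit_combined_model, roc_curve,
                   nagelkerke_r2, combined_misclassified)

cohort = apply_exclusions(load_table1_fixture())
print("analysis set:", cohort.group_sizes())

audit = classify_cohort(cohort, ThresholdRule("max", 2.48))
print(f"max > 2.48%: {audit.n_correct}/{audit.n_total} correct, "
      f"sens {100*audit.sensitivity:.1f}%, spec {100*audit.specificity:.1f}%, "
      f"errors {audit.misclassified_ids()}")

model = fit_combined_model(cohort)                      # mean + max + range
fitted = roc_curve(model.fitted, model.outcome == 1, positive=True)
print(f"combined model: AUC {fitted.auc:.3f}, Nagelkerke R2 {nagelkerke_r2(model):.3f}, "
      f"misclassified at 0.5: {combined_misclassified(model, cohort, 0.5)}")

df = cohort.df
r = roc_curve(df["aptw_mean"], df["group"], positive="HGG")
print(f"APTw mean ROC: AUC {r.auc:.3f}, cutoff {r.optimal_cutoff:.2f}%, "
      f"sens {100*r.sensitivity:.1f}%, spec {100*r.specificity:.1f}%")
```

prints

```
analysis set: {'HGG': 16, 'LGG': 6}
max > 2.48%: 21/22 correct, sens 93.8%, spec 100.0%, errors [7]
combined model: AUC 0.958, Nagelkerke R2 0.720, misclassified at 0.5: [3, 7, 17]
APTw mean ROC: AUC 0.896, cutoff 1.90%, sens 93.8%, spec 83.3%
```

Reading: on the 22-subject analysis set, a fixed threshold of 2.48 % on
the maximal APTw signal grades 21 of 22 gliomas correctly (the one miss is
an atypically low-signal glioblastoma); the combined logistic model of
mean, max and range separates the grades with an AUC of 0.958 and
misclassifies three subjects at the 0.5 probability threshold; and the
subject-mean APTw alone achieves AUC 0.896 with a Youden-optimal cutoff of
1.90 %. The same numbers, with the descriptive and Mann-Whitney tables,
come from `aptwq cohort-stats --out report.json` or `aptwq report`.

Image-level stages run on synthetic phantoms:

```sh
aptwq simulate-phantom --out phantom/ --shape 20,20,2 \
      --lesion 10,10,0,8.0,HGG,3.0 --noise-sd 0.002 --seed 1
aptwq compute-aptw --stack phantom/offset_stack.nii.gz \
      --s0 phantom/s0.nii.gz --out aptw.nii.gz
aptwq roi-stats --map aptw.nii.gz --lesion-mask phantom/lesion_mask.nii.gz \
      --exclusion-mask phantom/exclusion_mask.nii.gz
```

The last command prints the placed ROI and its statistics; the disc mean
lands within 0.1 pp of the phantom's high-grade target (2.60 %).

See `docs/methods.md` for the models, conventions, and design decisions.

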