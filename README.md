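# noduletex

Texture analysis of solitary pulmonary nodules (SPNs) in 2-D CT images.
A solitary pulmonary nodule is a single well-circumscribed lung opacity up
to 3 cm across; deciding whether one is benign or malignant from CT alone
is a long-standing computer-aided-diagnosis problem.  This package
implements, as a tested and reusable pipeline, a classification study
design built on **contourlet texture features**:

1. a rectangular region of interest (ROI) around the nodule is cleaned up
   by seeded region growing (background muscle/vessel pixels set to zero);
2. the ROI is decomposed by a **contourlet transform** — a Laplacian
   pyramid (LP) that isolates detail at dyadic scales, followed by a
   directional filter bank (DFB) that splits each scale into wedge-shaped
   orientation subbands; the default profile is 3 scales × 16 directions
   = **48 directional subbands**;
3. fourteen texture statistics (entropy, mean, correlation, energy,
   homogeneity, standard deviation, maximum probability, inverse
   difference moment, cluster tendency, inertia, sum-mean,
   difference-mean, sum-entropy, difference-entropy) are computed per
   subband — mean and SD on raw coefficients, the rest from a pooled
   symmetric gray-level co-occurrence matrix — giving **672 features**
   per ROI;
4. an SVM with Gaussian RBF kernel `K(x, z) = exp(-γ‖x−z‖²)` is evaluated
   by stratified 10-fold cross-validation on three dataset variants —
   19 patient-information variables only, texture only, and both — with
   seven assessment criteria: sensitivity, specificity, accuracy,
   precision, Youden index (sens + spec − 1), F-measure (β = 1) and ROC
   AUC;
5. the class imbalance (about 3.3 malignant ROIs per benign one) can be
   corrected by **SMOTE**: synthetic minority rows `x + u·(z − x)` with
   `z` one of the k = 5 nearest minority neighbours;
6. cohort statistics reproduce the usual group-comparison tables:
   uncorrected Pearson chi-square for binary variables, Welch's *t* for
   age and diameter, and a per-feature Mann–Whitney AUC screen with a
   Bonferroni threshold of 0.05/672 = 7.4e-5.

The hospital CT images behind the original cohort are not publicly
deposited, so the package ships a first-class **synthetic cohort
generator** that emulates the data's statistical structure (nodule discs
on cluttered backgrounds, class-dependent oriented texture, per-patient
ROI grouping, and a 19-variable patient table with the published
class-conditional marginals).  All claims the test suite makes about
classification behaviour are claims about these synthetic cohorts; see
`docs/methods.md` for exactly what that does and does not establish.

## Worked example

```python
from noduletex import CohortSpec, KernelConfig, cross_validate, generate_cohort
from noduletex.pipeline import RunConfig, assemble_datasets, featurize_cohort

spec = CohortSpec(n_benign_patients=10, n_malignant_patients=30,
                  rois_per_patient=(5, 7), image_size=64,
                  texture_contrast=0.6, seed=1)
cohort = generate_cohort(spec)
features = featurize_cohort(cohort, RunConfig())
print(f"{len(cohort.patients)} patients, {len(features)} ROIs, "
      f"{features.shape[1] - 4} texture features per ROI")

datasets = assemble_datasets(features, cohort.patients, which="all")
for name in ("info", "texture", "both"):
    rep = cross_validate(datasets[name], KernelConfig(seed=1),
                         folds=10, grouping="patient")
    print(f"{name:8s} AUC={rep.auc:.2f} sens={rep.sensitivity:.2f} "
          f"spec={rep.specificity:.2f} acc={rep.accuracy:.2f} "
          f"youden={rep.youden:.2f} F={rep.f_measure:.2f}")
```

prints

```
40 patients, 236 ROIs, 672 texture features per ROI
info     AUC=0.67 sens=0.84 spec=0.26 acc=0.70 youden=0.11 F=0.81
texture  AUC=0.77 sens=1.00 spec=0.14 acc=0.79 youden=0.14 F=0.88
both     AUC=0.79 sens=1.00 spec=0.21 acc=0.81 youden=0.21 F=0.89
```

The ordering — combined ≥ texture-only ≥ patient-information-only AUC —
is the study design's central comparison: adding contourlet texture to
clinical variables improves discrimination.  The low specificity at this
small cohort size reflects the 3:1 class imbalance (the SVM favours the
malignant majority), which is exactly what the SMOTE balancing step
addresses (`noduletex.smote`, or `--smote within-fold` on the CLI).

A command-line interface mirrors the library
(`noduletex simulate | segment | decompose | featurize | stats | balance |
evaluate | run-study | make-fixtures`); `noduletex run-study out/`
writes feature CSVs, the three-variant report, the per-family and
size-stratified reports, and a config-hash-stamped log.

## Cross-validation grouping

By default folds are stratified at the ROI level, mirroring the original
design.  Because every patient contributes many correlated ROIs (slices of
the same nodule), ROI-level folds let a classifier recognise the held-out
patient from training-set ROIs and inflate performance.  Pass
`grouping="patient"` to keep each patient's ROIs in one fold; the
package's own calibration tests use patient grouping throughout.

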