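# habitatrad

Habitat-aware, multiscale DCE-MRI radiomics for predicting axillary lymph
node metastasis (ALNM) in breast cancer.

## The problem

Whether a breast tumor has spread to the axillary lymph nodes drives
surgical and systemic treatment decisions, but the reference standard —
sentinel node biopsy — is invasive.  Radiomics on dynamic contrast-enhanced
MRI offers a noninvasive alternative; conventional whole-tumor signatures,
however, average away exactly the intratumoral heterogeneity and
peritumoral microenvironment that carry metastatic signal.  `habitatrad`
implements a multiscale pipeline for researchers building and evaluating
such models:

* **Habitat mapping** — each tumor is split into ~100 spatially constrained
  3D SLIC superpixels; 19 first-order statistics per superpixel, pooled over
  the training cohort, are clustered with K-means, the cluster count `K`
  chosen by maximizing the Calinski–Harabasz index
  `CH(K) = [B/(K−1)] / [W/(N−K)]` over K = 2..10.  Training centroids are
  frozen as a template so the same habitats are mapped in every cohort.
* **Peritumoral rings** — non-overlapping 0–1, 1–3 and 3–5 mm shells by
  Euclidean distance transform on the 1 mm isotropic grid.
* **IBSI-style feature panels** — an explicit 1,547-name default panel per
  region (14 shape + 306 first-order + 1,227 GLCM/GLRLM/GLSZM/NGTDM texture
  features over 17 derived images); the three-habitat signature has
  3 × 1,547 = 4,641 columns.  KNN imputation for features undefined on small
  subregions.
* **Selection cascade** — Mann–Whitney filter (p < 0.05) → iterative
  correlation pruning (|r| > 0.9) → mRMR top 32 → LASSO logistic with
  10-fold CV; nonzero coefficients define the Rad-score
  `intercept + Σ βⱼ·zⱼ`.
* **Models** — signature models (logistic / linear SVM / ExtraTrees, grid
  search over 5-fold CV AUC), a clinical model (univariate OR screen, ridge
  logistic), and a combined model (forward stepwise logistic over habitat
  score + 1 mm peritumoral score + clinical covariates, LRT entry p < 0.05).
* **Evaluation** — DeLong AUC CIs and paired tests, Youden-threshold
  confusion metrics, Hosmer–Lemeshow calibration, decision-curve net
  benefit `NB(t) = TP/N − FP/N·t/(1−t)`, exact/sampled SHAP attributions,
  and a nomogram points table.
* **Synthetic cohorts** — seeded 3D phantoms with texture-distinct
  subzones, a decaying peritumoral gradient, clinical covariates and
  logistic outcomes, so the whole pipeline is testable without patient data.

## Worked example

```python
import warnings
from habitatrad.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(output_dir="out", n_cases=40, grid_size=48, seed=7)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")        # small-cohort notices
    res = run_pipeline(cfg)

print("selected K:", res.template.K)
for sig, auc in res.aucs["validation"].items():
    print(f"{sig:>10}: {auc:.3f}")
```

Output:

```
selected K: 3
 radiomics: 0.778
   habitat: 0.833
   peri1mm: 0.667
   peri3mm: 0.472
   peri5mm: 0.333
  clinical: 0.500
  combined: 0.806
```

The template recovers the three planted texture zones (`K = 3`).  On the
held-out split the habitat signature (0.833) edges the whole-tumor
signature (0.778) — its subregion features measure the zone composition the
outcome was generated from directly — and the 1 mm ring is the strongest
peritumoral scale, mirroring the gradient planted just outside the margin.
At this small cohort size (40 cases, 12 held out) the AUCs are noisy and
the clinical model finds no significant covariates, falling back to the
training prevalence; larger cohorts give every signature more traction.

The same workflow is available from the shell:

```bash
habitatrad simulate --n 40 --grid 48 --seed 7 --out cohort/   # NIfTI + CSV
habitatrad run --set n_cases=40 --set grid_size=48 --set seed=7
```

## Layout

```
src/habitatrad/
  imaging.py     volumes/masks, NIfTI I/O, resampling, N4, Dice QC
  rings.py       peritumoral ring construction
  habitats.py    SLIC superpixels, CH index, habitat template
  features/      derived images, shape/first-order/texture engines, panels
  selection.py   univariate -> pruning -> mRMR -> LASSO cascade, Rad-score
  models.py      splits, signature/clinical/combined models
  evaluate.py    DeLong, metrics, HL, DCA, SHAP, nomogram
  synthetic.py   phantom and cohort generators
  pipeline.py    end-to-end orchestration with provenance hashing
  cli.py         `habitatrad simulate|run`
docs/methods.md  the full methods note
```
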