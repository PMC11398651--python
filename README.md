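# dcect-radiomics

Reproducibility analysis of radiomic texture features on dynamic
contrast-enhanced CT (DCE-CT) of hepatocellular carcinoma (HCC), with a
synthetic phantom so the whole chain runs without patient data.

DCE-CT acquires a rapid series of CT volumes while injected contrast
transits the liver; the series is labelled into non-contrast (NCE), late
arterial (L-AP) and portal venous (PVP) phases. Radiomic features extracted
from a tumor segmentation depend on *which* sequence is analyzed and on
*who* segmented the tumor. This package quantifies both effects and then
asks whether the features that survive them still predict histologic grade.

The pipeline, mirroring a 39-patient HCC study design:

1. **Phantom cohorts** (`dcect_radiomics.phantom`) — ellipsoidal lesions
   with logistic arterial enhancement and exponential venous washout, a
   grade-linked correlated texture field, two observer segmentations
   calibrated to a Dice overlap of 0.79, optional per-sequence intensity
   drift, all seeded and bit-reproducible.
2. **Feature extraction** (`dcect_radiomics.features`) — a fixed registry of
   127 named features in 12 classes (first-order, GLCM, run length, GTDM,
   Gabor, Laws, LoG, wavelet, sigmoid edge, edge frequency, fractal
   dimension, spatial correlation), computed slice-wise on the native grid
   with 25 HU intensity bins anchored at the in-mask minimum.
3. **Concordance** (`dcect_radiomics.concordance`) — Lin's concordance
   correlation coefficient

   CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²),

   cutoff 0.90; Dice overlap; the 2 + 7 + 7 sequence-selection rule (first
   two, middle three, last two); inter-observer, pairwise inter-sequence
   (16×16) and intra-phase reproducibility; Spearman-based pruning of
   correlated features (|ρ| > 0.90).
4. **Grade models** (`dcect_radiomics.grading`) — Wilcoxon rank-sum group
   tests, stratified 29/10 split, SMOTE balancing, treebag recursive feature
   elimination (max 3 features, 5-fold CV) and an XGBoost classifier
   reporting AUC, sensitivity, specificity, NPV and PPV.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/02_extract_features.py
python analysis/03_interobserver.py
```

prints (12-patient desk cohort, seed 17):

```
simulated 12 patients (2 low-grade, 10 higher-grade)
mean observer Dice 0.788 (target 0.79)
extracted 48768 records (384 sequence-observer pairs x 127 features) in 35s
NCE  :  51/127 features reproducible between observers (CCC >= 0.90); 11 remain after pruning
L-AP :   8/127 features reproducible between observers (CCC >= 0.90); 6 remain after pruning
PVP  :  10/127 features reproducible between observers (CCC >= 0.90); 7 remain after pruning
```

Reading this: the two observers' masks overlap at the calibrated Dice of
0.79; in the unenhanced phase, where lesion-background contrast is low, the
mask disagreement barely moves the feature values (51 of 127 features have
CCC ≥ 0.90 across patients in every NCE sequence), while in the enhanced
phases the same mask disagreement changes the sampled tissue much more, so
far fewer features are observer-reproducible. Pruning then collapses each
set to its non-redundant core. `04_phase_reproducibility.py` adds the
16×16 pairwise matrix per observer (agreement decaying with the index gap
between sequences), `05_drift_sensitivity.py` shows the median pairwise
count falling as per-sequence drift grows, and `06_grade_classification.py`
simulates 39 patients (7 low-grade / 32 higher-grade) and trains the
boosted-tree grade models on the reproducible sets.

A `dcect` CLI wraps the same stages (`simulate`, `extract`, `concordance
--mode {interobserver,pairwise,intraphase}`, `prune`, `stats`, `classify`,
`run-all`), driven by a flat `key: value` config file; external feature
tables in wide CSV form can be ingested with `dcect ingest`, with
underscore/spacing header variants normalized against the registry.

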