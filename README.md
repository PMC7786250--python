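# nwuct

Net water uptake densitometry and histogram radiomics for non-enhanced head
CT, aimed at early prediction of malignant cerebral edema (MCE) after middle
cerebral artery (MCA) stroke.

## The problem and the method

Ischemic brain tissue takes up water, which lowers its CT density
(hypoattenuation). The fractional **net water uptake** of a lesion can be
inferred from an ordinary non-enhanced admission scan by comparing the mean
density of ischemic tissue with that of the mirrored contralateral tissue:

```
NWU = 1 − D_ischemic / D_normal
```

where `D_ischemic` and `D_normal` are mean densities in Hounsfield units.
This package implements two estimators and everything around them:

- **IP-NWU** (image-patch NWU): four mirrored pairs of 30×30-voxel patches
  placed on the affected and unaffected MCA territories. No lesion
  segmentation or perfusion imaging is needed.
- **SR-NWU** (segmented-region NWU): a lesion segmentation (e.g. from a
  follow-up scan) aligned into a symmetric template space by a 12-dof affine
  transform, overlaid on the admission image and mirrored across the
  midsagittal plane.
- **Histogram radiomics**: the voxel-wise NWU maps of the four patch pairs
  (elements in [0, 1]) are binned into an 8-grade histogram `h(r_n) = Y_n`;
  from the counts `Y_1..Y_8` five parameters are derived — population std
  `s`, min-to-max slope, Shannon entropy `H = −Σ pₙ log₂ pₙ`, skewness
  `g = Σ(Yᵢ−Ȳ)³/(N s³)` and excess kurtosis `k = Σ(Yᵢ−Ȳ)⁴/(N s⁴) − 3` —
  13 imaging features in total.
- **Prediction models**: SVM / logistic-regression / random-forest
  classifiers on feature sets (NWU + clinical, NWU + imaging, all),
  evaluated by leave-one-out cross-validation with ROC/AUC, Youden cutoff,
  full confusion-matrix metrics including the Matthews correlation
  coefficient, and DeLong's paired-AUC test.
- **Agreement statistics**: ICC(2,1), Bland-Altman limits of agreement, and
  two-group descriptive tests (t-test, chi-squared).
- **Synthetic ground truth**: a bilaterally symmetric head phantom whose
  lesion density is `parenchyma_HU × (1 − w)` for a known uptake `w`, plus a
  cohort generator (39 MCE / 77 non-MCE by default, group mean uptakes
  18.2% / 8.5%) so the entire pipeline is testable without patient data.

## Worked example

`examples/phantom_ipnwu.py` builds a noisy phantom with true uptake 0.182
and recovers it from four mirrored patch pairs:

```
true uptake w:        0.182
pooled IP-NWU:        0.183
per-pair NWU:         [0.183, 0.186, 0.177, 0.184]
D_ischemic / D_normal: 26.98 / 33.01 HU
map voxels clamped:   47 of 3600
```

The pooled estimate sits within half a percentage point of the truth: the
density ratio inverts the multiplicative attenuation model exactly and
averaging 3600 voxels suppresses the 2-HU scanner noise. The other scripts
in `examples/` cover the histogram features, cohort-level prediction
(`cohort_prediction.py` prints a univariate NWU AUC of 0.906 against an RF
NWU+imaging LOOCV AUC of 0.906 vs 0.843 for RF on NWU alone, DeLong
p = 0.018 on the default seed), region-vs-patch agreement and registration,
and placement-jitter reliability (ICC(2,1) ≈ 1.0).

A thin CLI mirrors the library:

```bash
nwuct simulate --n-mce 39 --n-non-mce 77 --seed 1 --out-dir cohort --volumes
nwuct nwu --image cohort/mce-000.nii.gz --patches patches.csv --out nwu.json
nwuct features --nwu-json nwu.json --set all --age 64 --gender F --nihss 12 --out feat.csv
nwuct predict --features features.csv --classifier rf --out report.json
nwuct agreement --table ratings.csv --method icc
```

## Layout

- `src/nwuct/volumes.py` — CT volume I/O (NIfTI, DICOM series), phantom and
  cohort generators
- `src/nwuct/patches.py` — mirrored-patch placement, validation, IP-NWU,
  voxel-wise ratio maps
- `src/nwuct/regions.py` — affine registration, mask transfer, mirroring,
  SR-NWU
- `src/nwuct/features.py` — NWU histogram and the 13 imaging features
- `src/nwuct/prediction.py` — LOOCV, ROC/AUC, Youden, DeLong, RF grid search
- `src/nwuct/agreement.py` — ICC, Bland-Altman, cohort comparisons
- `src/nwuct/pipeline.py` — cohort → feature-table convenience layer
- `docs/methods.md` — models, assumptions, parameter choices, limitations
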