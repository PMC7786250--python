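# Methods

## Densitometric model

Water uptake in ischemic tissue dilutes its X-ray attenuation. The package
models a lesion voxel's density as the contralateral (healthy) density
scaled by `1 − w`, where `w` is the fractional water uptake. Net water
uptake inverts this model:

```
NWU = 1 − D_ischemic / D_normal
```

`D_ischemic` and `D_normal` are mean Hounsfield densities of homologous
tissue on the two hemispheres. Because NWU is a ratio of densities it is
invariant under a global multiplicative intensity rescale, but **not** under
an additive offset — a miscalibrated HU zero shifts NWU. Both properties
are tested.

### Image-patch NWU (IP-NWU)

Four mirrored pairs of 30×30-voxel patches are measured on reference axial
slices. Mirroring is reflection across the midsagittal plane, taken to be
the column midline of the volume (`col → n_cols − 1 − col`, 0-based; the
axis convention is `(slice, row, column)` throughout). Within a pair, the
patch with the lower mean HU is designated ischemic; exact ties defer to a
declared side and are otherwise an error. Patch extent is the half-open
window `[c − 15, c + 15)` per in-plane axis.

Two ways of combining the four pairs are provided. The default, *pooled*,
treats all 3600 ischemic voxels as one sample and all 3600 normal voxels as
another and applies the formula once — a single "density of the ischemic
core" reading. The alternative averages the four per-pair NWU values; both
are always reported and they differ only at second order.

Patch validation is report-only: a patch is flagged when more than 10% of
its voxels fall below 20 HU (CSF contamination inflates NWU) or any voxel
exceeds 100 HU (bone). The thresholds are package defaults chosen from
typical head-CT tissue ranges; expert placement is expected to avoid such
patches, and automated placement is out of scope.

### Voxel-wise maps and clamping

Each ischemic voxel is divided by its mirror-image voxel (the normal patch
column-flipped), giving four 30×30 maps of per-voxel NWU. Values outside
[0, 1] — negative when noise makes an ischemic voxel denser than its
mirror — are clamped into the range and counted rather than dropped, so the
histogram always conserves its 3600 voxels. Voxels whose denominator is at
or below 1 HU are excluded (NaN) and counted separately; this happens only
for non-physical inputs.

### Segmented-region NWU (SR-NWU)

A lesion mask (in practice segmented on a follow-up scan) is brought onto
the admission image in a common symmetric space, mirrored, and the same
formula applied to the two mask means. Voxel positions are excluded
*jointly* when either the lesion voxel or its mirror falls outside a 5–100
HU parenchymal window, suppressing CSF/bone contamination symmetrically.
A `slices` argument restricts the measurement to chosen axial levels.

Registration is a 12-degree-of-freedom affine estimated with SimpleITK:
dense sampling (deterministic), geometry-centred initialisation, a 3-level
multi-resolution pyramid, regular-step gradient descent. The objective is
**negative correlation** by default: admission, follow-up and template are
all CT-like images with a linear intensity relationship, for which
correlation is the sharp criterion, whereas Mattes mutual information —
offered via `metric="mattes"` — has a degenerate optimum (scale collapse)
on near-piecewise-constant synthetic heads and is only preferable across
modalities. A shipped synthetic symmetric head substitutes for a standard
brain template so that nothing needs downloading; a real template volume
can be passed by path.

## Histogram features

The retained map voxels are binned into `N = 8` equal-width grades over
[0, 1] (half-open bins, last bin closed), giving counts `Y_1..Y_8`. Five
parameters summarise the count vector:

- population standard deviation `s` (1/N normalisation, consistent with the
  N in the moment formulas);
- slope: `(Y_max − Y_min) / (i_max − i_min)` with 1-based grade indices,
  first occurrence on ties, 0 for a constant vector;
- Shannon entropy `H = −Σ pₙ log₂ pₙ` with `0·log 0 = 0`; bounded by
  `log₂ 8 = 3` bits. (The raw sum `Σ p log p` is non-positive; the sign and
  base-2 convention make `H` the average information content, with a
  natural-log option.)
- skewness `g = Σ(Yᵢ−Ȳ)³/(N s³)` and excess kurtosis
  `k = Σ(Yᵢ−Ȳ)⁴/(N s⁴) − 3`, population moments of the *grade-count
  vector* — deliberately moments of `Y`, not of the raw map values; a
  `moments_on="values"` flag computes the alternative reading. Zero-variance
  vectors are degenerate and report 0 with a flag.

Feature sets follow the study design: `nwu_clinical` = (NWU, age, gender,
NIHSS), `nwu_imaging` = NWU + the 13 imaging features, and the 17-value
union. Gender is encoded F=1/M=0; ordering is fixed and documented in the
`FeatureVector`.

## Prediction and evaluation

Classifiers are scikit-learn's SVM (RBF), logistic regression and random
forest with library defaults; the random-forest hyperparameters
`random_state ∈ {2,4,…,16}` and `n_estimators ∈ {100,…,1000}` can be grid
searched, scored by whole-LOOCV AUC with ties broken toward the smaller
forest. The grid search sits outside the LOOCV rather than nested within
each fold; this matches the apparent study procedure but is mildly
optimistic — a caveat, not a bug, and a nested variant would multiply cost
by the fold count.

LOOCV runs one fold per subject. Z-score standardisation is applied for the
scale-sensitive SVM and LR (statistics from the training fold only, so
nothing leaks from the held-out subject) and not for the scale-equivariant
random forest. Metrics are computed on the pooled held-out scores and
predicted labels: ACC/SEN/SPE/PPV/NPV/F1 and MCC (0 with a flag when a
margin is empty), ROC and trapezoidal AUC (equal to the Mann-Whitney
probability with ties counted ½), the Youden-optimal cutoff (lowest
threshold on ties), and DeLong's two-sided test for paired AUCs via midrank
structural components. Identical or rank-equivalent score vectors give
p = 1; a zero-variance difference with unequal AUCs is an error.

One property of pooled LOOCV worth knowing: under the null (labels carry no
information) the pooled-score AUC is *pessimistically* biased below 0.5,
because each held-out subject's training prior is slightly anti-correlated
with its own label. The suite pins this from both sides (no optimism, known
conservatism) rather than asserting exact 0.5.

Printed-report rounding uses half-up at 2 decimals. A helper reconstructs
the unique integer confusion matrix consistent with a printed
sensitivity/specificity pair and known group sizes, erroring out when the
printed precision does not identify one.

## Synthetic phantom and cohort

The phantom is a bilaterally symmetric head: elliptical skull ring (700
HU), parenchyma (33 HU), two symmetric ventricles (5 HU), air background
(−1000 HU), built from symmetric functions of the column offset so the
noise-free, lesion-free volume is *exactly* mirror-symmetric. An
MCA-territory lesion (a lateral elliptical cylinder over a slice range) is
set to `33 × (1 − w)` before i.i.d. Gaussian noise (default SD 2 HU);
overlap of the lesion with ventricles or skull is a generation error.
Default grid: 24 slices of 512×512 voxels at (5, 0.449, 0.449) mm, matching
a typical axial-head protocol. An optional per-voxel uptake dispersion
(`lesion_texture_sigma`) makes the lesion heterogeneous, and an optional
misalignment (in-plane rotation + voxel shift) simulates a second
acquisition for registration tests.

The cohort generator draws 39 MCE / 77 non-MCE subjects by default with
group mean uptakes 0.182 / 0.085 (SD 0.05, truncated to [0, 0.95]),
covariates from the corresponding group distributions (age 64.23±11.39 vs
65.79±12.05; female rate 0.333 vs 0.416; NIHSS 11±6.83 vs 15±2.94;
onset-to-scan times 8.28±6.53 vs 5.32±4.11 h first, ~36±10 h second), and
an onset-time effect `w += rate·(log(t+1) − E[log(t+1)])` (rates 0.010 /
0.004 per log-hour) centred so the group means are preserved while uptake
still increases with time within groups. Within-lesion uptake dispersion
differs by group (mean SD 0.12 vs 0.07, subject-level SD 0.04/0.03, floor
0.01): malignant edema is the more heterogeneous process, and this is the
mechanism by which the histogram features carry group information beyond
the mean — without it, every imaging feature would be a deterministic
function of `w` plus noise and no multivariate model could beat the mean.
Cohort volumes default to 4 slices of 192×192 with the lesion spanning all
slices; this preserves every geometric relation the measurements depend on
(patch fit, mirror symmetry, CSF/skull adjacency) at a fraction of the
cost, and the simulation sizes quoted below refer to this grid.

What the generator does *not* emulate: real anatomy and atlas variability,
partial-volume and beam-hardening effects, spatially correlated noise,
placement error that misses the lesion, and segmentation error in the
SR-NWU mask (the ground-truth mask stands in for a human segmentation, and
is labelled synthetic). Passing tests therefore demonstrate correctness of
the estimators under the stated physical model, not clinical performance.

## Verification strategy and problem sizes

- Uptake recovery: pooled IP-NWU vs true `w ~ U(0.02, 0.30)` over 200
  noise-SD-2 phantoms, MAE ≤ 0.01.
- Method agreement: IP-NWU vs SR-NWU Bland-Altman bias within ±0.01 over
  the same 200 phantoms.
- Model ordering: RF on NWU+imaging vs RF on NWU alone (same classifier,
  same LOOCV — the like-for-like version of the feature-set comparison),
  won in ≥ 80% of 12 synthetic cohorts of n = 116. Twelve seeds keep the
  12×2 LOOCV runs (each ~20 s at 100 trees on one CPU) affordable; scouting
  margins were well clear of the threshold.
- Oracle equivalence: AUC vs all-pairs counting; DeLong vs a
  10,000-replicate paired bootstrap within 0.03; histogram counts vs a
  per-voxel loop; ICC (pingouin) vs the brute-force ANOVA mean-squares
  formula to 1e-10.
- Conservation and normalisation: ΣYₙ = 3600 retained voxels, map range
  [0, 1], entropy ≤ 3 bits, MCC ∈ [−1, 1], mirror operations are
  involutions.

## Agreement statistics

ICC defaults to ICC(2,1) — two-way random effects, absolute agreement,
single measurement — the standard form for interchangeable raters;
ICC(3,1) is available. Zero between-subject variance is degenerate (NaN).
Bland-Altman uses `d = x − y`, limits `bias ± 1.96·SD(d)` (sample SD), and
a paired two-sided t-test of the differences for the bias p-value. The
test-retest harness measures 30 phantoms twice with patch centres jittered
by up to ±2 voxels (between-subject variance is required for an ICC, so
repeated measurement of a single phantom would be uninformative).

## Numerical conventions and degenerate inputs

Half-open patch windows; 0-based indices everywhere except the 1-based
grade indices inside the slope formula; histogram bins half-open with the
last closed at 1; classification tie tolerance 1e-9 HU; denominator floor
1 HU for map voxels; `D_normal ≤ 0` is always an error (non-physical
parenchyma). Cohort and phantom generation are pure functions of their
spec + seed. Seeds derived from a user seed stay below 2³¹.

## Known limitations

- No automatic patch placement; coordinates are inputs (the synthetic
  placement helper centres patches in the lesion mask and is not a
  detector).
- Registration is linear only; no nonlinear refinement, and the synthetic
  template has no anatomical detail beyond the skull/ventricle layout.
- F1 as printed in the source study is not consistently recoverable from
  its printed counts, so F1 is reported but never used as a verification
  quantity.
- The phantom's noise is white; real CT noise is correlated and
  dose-dependent, so real-data NWU precision will be somewhat worse than
  the phantom bounds suggest.
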