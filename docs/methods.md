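# Methods

`deltarad` implements a longitudinal ("delta") radiomics analysis for
contoured 3D image series, of the kind used to predict genitourinary (GU)
toxicity from daily prostate cone-beam CT during radiotherapy. This note
records the model, the numerical conventions, the synthetic study design,
and the places where a genuine design choice had to be made.

## Feature extraction

**Preprocessing.** Image processing is deliberately minimal: no
resampling, filtering, or range re-segmentation. Within the effective ROI
the intensities are discretized with a fixed bin number (default
`n_bins = 256`, i.e. 8-bit) over the per-image in-mask min/max:

    level(v) = floor(n_bins * (g(v) - g_min) / (g_max - g_min)) + 1,

clamped so the maximum maps to `n_bins`. A flat ROI (`g_max == g_min`)
maps every voxel to level 1 and raises a flag; downstream features then
apply their own degenerate rules (Correlation missing, NGTDM Coarseness
capped at 10^6, Contrast 0). Degenerate features are always explicit
missing values (NaN), never silent zeros, so a bad feature cannot
contaminate a bin average unnoticed.

**Fiducial artifacts.** Gold fiducial markers produce bright artifacts
inside the prostate. The exclusion mask is built by thresholding in-ROI
intensities and dilating by an ellipsoid of configurable millimetre
radius (default 2 mm for real data); the effective ROI is the contour
minus this exclusion. Threshold + dilation is this package's stand-in for
a clinical artifact-masking algorithm whose details are not public; both
parameters are exposed in config.

**Texture classes.** Five classes, 42 features total (roster
config-overridable): 4 first-order ("Global") statistics on raw in-mask
intensities, 8 GLCM, 8 GLRLM, 11 GLSZM, 5 NGTDM, plus volume-normalized
(VN) companions of six volume-sensitive features. Matrix conventions:

- Neighbour offsets are in voxel units; anisotropic spacing is ignored in
  neighbour definitions (the near-universal convention).
- GLCM: pairs at Chebyshev distance 1 (configurable) along the 13 unique
  3D directions, counted only when both voxels are in the effective mask,
  summed over directions, symmetrized, normalized to probabilities. The
  direction-merged matrix (rather than per-direction feature averaging)
  was chosen for simplicity and rotational robustness.
- GLRLM: maximal equal-level runs along the same 13 directions, truncated
  at the mask boundary, summed over directions.
- GLSZM: zones are maximal 26-connected equal-level components.
- NGTDM: per level i, `n_i` counts in-mask voxels with at least one
  in-mask 26-neighbour and `s_i` sums |i − mean neighbour level|.

**Volume normalization.** Six features scale systematically with voxel
count N: the grey-level/run-length non-uniformities (GLRLM GLN/RLN, GLSZM
GLN) and NGTDM Busyness grow ∝ N, while NGTDM Coarseness and Strength
shrink ∝ 1/N. The VN variant multiplies by `N**k` with k = −1 or +1
accordingly; the exponent table is part of the public API. Tiling a
texture block to twice its volume moves each raw feature by ≈ its volume
power and its VN companion by ≤ 5% (boundary/zone-merge effects account
for the residual drift).

## Delta features and BED binning

The delta-radiomic feature of fraction N is the relative change from the
first fraction, `DRF = (RF_N − RF_1) / |RF_1|`. A zero or missing
baseline makes the whole trajectory missing (not ±∞), keeping bin means
finite. DRF is scale-invariant: rescaling a feature's trajectory by c > 0
leaves it unchanged, and c < 0 flips its sign.

To pool patients with different fractionation schedules, per-fraction
DRFs are averaged within bins of cumulative biologically effective dose,
`BED(f) = Σ_{k≤f} d_k (1 + d_k / (α/β))` with α/β = 3 Gy for prostate and
a 20 Gy bin width (roughly one treatment week at conventional
fractionation). Bins are right-closed, left-open from zero: a cumulative
BED of exactly 20.0 Gy falls in bin 1 (ties go to the lower bin, with a
10⁻⁹ relative tolerance against float noise). Fraction 1 (DRF ≡ 0) is
included in bin 1; since every patient contributes the same zero there it
only shrinks bin-1 contrasts slightly, and keeping it makes bin
membership a pure function of the schedule.

Covariates (prostate volume at fraction 1, baseline symptom score) enter
the model matrix untransformed as their own columns, not as DRFs.

## Model building

Per clinical endpoint (acute GU, sub-acute GU, dichotomized ΔIPSS):

1. **Ranking.** Random-forest Gini (mean impurity decrease) importance on
   the full patients × (feature, bin) matrix, all BED bins pooled;
   per-feature importance is the maximum over that feature's bin columns
   (the pooling aggregation is unstated in the workflow this follows;
   maximum favours features that are strong somewhere over features that
   are mediocre everywhere). 500 trees by default, seeded. Missing cells
   are median-imputed before the fit.
2. **Decorrelation.** Greedy pass in rank order: drop a feature iff its
   |Spearman ρ| with an already-kept feature is strictly > 0.8, computed
   on pooled-bin values with pairwise-complete observations. Spearman is
   used for rank-robustness and consistency with the QA analysis.
3. **Selection.** Keep up to the top seven survivors. A paired
   manual/automated comparison uses the feature set selected on the
   manual arm for both arms, so model differences reflect the contours,
   not the selection.
4. **Per-bin models.** Logistic regression with leave-one-out cross
   validation: each training fold is median-imputed and standardized on
   its own statistics; the fit is near-unpenalized (C = 10⁶) unless any
   fold fails to converge (perfect separation is common at n ≈ 50 with 7
   features), in which case all folds are refit uniformly with a fixed
   ridge penalty (C = 1). Each patient's score is the held-out predicted
   probability **minus the training fold's class prevalence**: pooled raw
   LOO probabilities are label-linked (leaving out a positive lowers the
   fitted base rate, depressing exactly that patient's score), which
   biases the null AUC far below 0.5; prevalence-centering removes the
   shift and leaves informative rankings intact.
5. **Summaries.** AUC is the Mann–Whitney statistic (midranks for ties).
   Its distribution comes from 1000 class-stratified bootstrap resamples
   of the (score, label) pairs — stratification guarantees both classes
   in every resample — summarized by the median and the 2.5/97.5
   percentile CI. Bins with fewer than two patients per class are skipped
   with a logged reason.
6. **Paired comparison.** The DeLong correlated-ROC test runs on the raw
   (un-resampled) paired LOOCV score vectors, using the placement-value
   (structural-component) covariance estimator; two-sided normal p,
   threshold 0.05, no multiplicity correction across bins (raw per-bin
   p-values are reported). Identical score vectors give p = 1 by
   convention; zero variance with unequal AUCs is an error.
7. **Snapshot models.** A baseline (planning-image-style) model per arm
   is fit on raw fraction-1 feature values of the selected features with
   the same LOOCV + bootstrap machinery, for the delta-vs-snapshot
   comparison.

**QA.** Contour agreement uses TG-132-style metrics: Dice coefficient,
mean distance-to-agreement (symmetrized mean of both directed mean
surface distances over voxel boundaries — the common convention; a
surface-mesh variant would differ at the sub-voxel level), centre-of-mass
displacement, and percent volume difference signed relative to the manual
mask. Feature consistency between arms is per-feature Spearman
correlation across patients at fraction 1, Benjamini–Hochberg adjusted
over the feature family at α = 0.05.

## Synthetic cohort

The generator produces the statistical structure the analysis assumes,
not CBCT physics (no scatter, beam hardening, or reconstruction, and no
DICOM). Defaults emulate a conventionally fractionated prostate cohort:
50 patients, 80 Gy/40 fx and 70.2 Gy/26 fx schedules (2:1), 0.9 × 0.9 ×
2 mm voxels, ellipsoidal prostate-like ROIs (±15% per-patient radius
jitter), automated contours at DSC ≈ 0.89, ~17% of the ROI excluded by
fiducial artifacts.

- **Texture.** Each fraction's image is a fresh Gaussian-random-field
  realization: white noise smoothed with an isotropic kernel (default
  correlation length 2 mm), rescaled to zero mean/unit variance, plus
  independent voxel noise (sd 0.1). Redrawing the field every fraction is
  what gives the delta features their day-to-day sampling noise — the
  noise floor both contour arms share, analogous to scan-to-scan
  variability in real daily imaging. (An early design used one persistent
  field per patient; that made the manual arm's delta features nearly
  deterministic and its models unrealistically strong.)
- **Outcome-linked drift.** The smoothing length — not the mean intensity
  — drifts linearly with fraction index, so texture-class delta features
  carry the signal while the first-order mean does not. The per-patient
  slope is drawn from N(drift_effect_size, 0.25·|drift_effect_size|) for
  latent responders and N(0, ·) otherwise (default 0.06 mm/fraction:
  a responder's correlation length roughly doubles over 40 fractions).
  Acute GU equals the latent responder label; sub-acute GU flips it with
  probability 0.15; ΔIPSS adds an outcome-linked shift (default +5) plus
  noise to an integer baseline and is dichotomized at "any increase"
  (threshold configurable — dichotomization rules are study choices).
- **Automated contours.** The manual mask is thresholded against its
  signed distance transform times a smooth random error field; the
  amplitude is bisected per fraction until DSC is within ±0.005 of the
  target (default 0.89). An unreachable target raises a generation error
  rather than clipping. The error field mixes a persistent per-patient
  component with a 30% per-fraction refresh, because deformable-
  registration errors are largely systematic; fully independent
  per-fraction boundary noise would make the automated arm's delta
  features unrealistically noisy.
- **Fiducials.** Three cross-shaped bright markers (intensity 8, ~6 sd
  above texture) placed in the ROI interior; the stored exclusion mask
  dilates them by 4.3 mm, chosen to reproduce an average ~17% ROI volume
  loss on the default geometry.

What passing tests on this phantom do **not** show: robustness to CBCT
reconstruction artifacts, scatter, motion, or inter-observer contour
variability; behaviour of Hounsfield-calibrated intensities; or clinical
effect sizes — the drift mechanism is one latent parameter, whereas real
toxicity signals are heterogeneous. Snapshot (fraction-1) models are
chance-level on the phantom by construction: the outcome influences only
the drift, not the baseline texture, whereas real baseline anatomy can
itself be predictive.

## Problem sizes and numerical choices

The test suite runs the cohort-level checks at reduced size (16 × 16 × 10
grids, ~400-voxel ROIs, 30 Gy/10 fx giving three 20 Gy BED bins, 24–100
patients, 100–200 bootstrap resamples and 200 RF trees), sizes chosen so
the full suite completes in a few minutes while keeping ≥ 10 fractions
and ≥ 3 bins per patient. `scripts/acceptance.py` uses the default
phantom geometry with 40 patients, the two clinical schedules, 500 trees
and 1000 bootstrap resamples. Statistical calibration checks use 2000
simulated null pairs at n = 50.

Tie-breaks and degenerate inputs: equal-importance features rank
alphabetically (deterministic); a constant feature inside a training fold
standardizes with unit variance; an all-missing column imputes to zero
after median imputation; Spearman pairs with < 3 complete observations
are skipped in the decorrelation pass; single-class outcomes and empty
masks raise errors rather than returning values.

## Known limitations

- The exact 42-feature roster of the motivating analysis is not public;
  the default roster implements every named feature and completes each
  class with standard members. Formula variants (e.g. per-direction GLCM
  averaging) would change feature values but not the pipeline contracts.
- LOOCV + full-data feature selection is optimistically biased (the
  selection sees all labels); the null-cohort AUC median sits near 0.6
  rather than 0.5. This mirrors the analysis design the package
  implements; an outer selection loop would remove it at the cost of
  departing from that design.
- DeLong's normal approximation is slightly anticonservative below
  n ≈ 30; the calibration test pins the type-I error at n = 50.
- The NIfTI reader assumes axis-aligned affines (diagonal spacing).
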