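# Methods

`nodtex` implements a quantitative-imaging pipeline for discriminating two
kinds of solid pulmonary nodule on chest CT — non-calcified hamartoma
(NCH, benign) and lung adenocarcinoma (ACA, malignant) — from a 94-feature
texture/attenuation panel and a small feedforward neural network. This
note records the models, the conventions the implementation fixes, and the
design choices made where the procedure admitted more than one reasonable
reading.

## ROI representation and preprocessing

A lesion is a binary 3D mask over a CT volume in Hounsfield units (HU).
Masks are converted to an *ROI list* of per-voxel records `(x, y, z, HU)`
with 0-based indices, `(x, y)` = (column, row) of the axial slice and `z`
the slice index, ordered by `z`, then `y`, then `x`.

Attenuation is normalized **per lesion** between `mu ± 3·sigma`
(`mu`, `sigma` = ROI mean and sample standard deviation, `ddof=1`):

    v  ↦  clip( (v − (mu − 3 sigma)) / (6 sigma), 0, 1 )

A constant ROI (`sigma = 0`) maps to 0.5 so degenerate phantoms remain
processable. Normalizing per lesion (rather than per scan) targets
inter-scanner variability at the level where features are computed; it
also makes every feature except the mass `f1` invariant under positive
affine HU transforms, a property the tests assert.

2D texture features are computed on the **maximum-area axial slice** (ties
broken toward the smaller index). The normalized values on that slice are
decimated to **8 gray levels** with equal-width bins on [0, 1]:
`level = 1 + floor(8 v)`, with `v = 1` assigned level 8.

## The 94-feature panel

The layout is a frozen contract: `f1–f8` attenuation, `f9–f88` GLCM
(20 features × orientations 0°, 45°, 90°, 135°), `f89–f94` LBP.

**Attenuation (f1–f8).** `f1` is the mean raw HU ("mass per voxel").
`f2–f4` are the parameters of the logistic `f(x) = f2 / (1 + e^{−(x−f3)/f4})`
fitted by least squares. The quantity being fitted is not uniquely pinned
down by the procedure's description; this implementation fits the
**empirical cumulative fraction** of normalized attenuation (x = sorted
value, target = Hazen plotting position `(i−0.5)/n`), the only monotone
sigmoid-shaped summary derivable from an unordered voxel list. This is an
artifact convention, not a claim about the original intent.
Initialization is `f2=1, f3=median, f4=sd/2`; tolerance `1e−8`, at most
500 function evaluations; non-convergence returns the best iterate with a
flag. `f5–f8` are mean, sample sd, skewness and excess kurtosis of the
normalized values. Skew/kurtosis use bias-uncorrected standardized central
moments (`m3/m2^1.5`, `m4/m2² − 3`), defined as 0 when the variance is 0.

**GLCM (f9–f88).** Co-occurrence matrices are 8×8, computed at unit pixel
displacement on each orientation, restricted to pixel pairs with **both
endpoints inside** the in-slice mask (preventing background
contamination), symmetrized and normalized to sum 1. Displacement vectors
in (row, col): 0°→(0,1), 45°→(−1,1), 90°→(−1,0), 135°→(−1,−1). The 20
features per orientation follow the standard Haralick-family definitions
with base-2 logarithms and `0·log 0 = 0`; sum variance uses the
sum-average convention; "normalized inverse difference (moment)" are
`Σ p/(1+|i−j|/N)` and `Σ p/(1+(i−j)²/N²)` with `N = 8`; correlation and
the information measures of correlation are defined 0 when their
denominators vanish. The per-orientation blocks are also averaged into 20
*pooled* features for group statistics.

**LBP (f89–f94).** Rotation-invariant uniform (riu2) codes on the square
8-neighborhood at radius 1, computed on the *continuous* normalized values
(quantization is introduced only for the co-occurrence analysis): a
neighbor ≥ center sets its bit; uniform patterns (≤ 2 circular
transitions) map to their set-bit count 0–8, non-uniform to 9 — a
10-symbol alphabet, so the code entropy is bounded by log₂10. Codes are
defined only where the full 8-neighborhood is masked. Features: moments of
the code values (conventions as above), the mean height of the occupied
bins of the normalized code histogram (the "histogram mean"; the
occupied-bin mean avoids a value that is constant by construction), and
the base-2 histogram entropy.

## Group statistics and classification

Per-feature group comparisons are **Welch** two-sample t-tests (the safer
default when variances are unknown), Bonferroni-corrected: threshold
`0.05/94 ≈ 0.0005` over the full panel and `0.05/20 = 0.0025` over the 20
pooled GLCM features. A feature with zero variance in both groups gets
`p = 1` if the means agree, else an exact-separation flag.

The classifier is a feedforward network — input = feature-set size, one
hidden layer of 50 tanh units, 2-unit softmax output, cross-entropy loss
(sklearn's `MLPClassifier`) — evaluated under stratified 10-fold
cross-validation repeated for a configurable number of cycles with fold
assignment reseeded per cycle. Per fold, features are min-max scaled **on
training rows only**; the early-stopping/validation machinery likewise
never sees test rows (a leakage test perturbs test rows and checks
training artifacts are unchanged). Test-fold scores are pooled within a
cycle; sensitivity, specificity, accuracy, PPV and NPV (percent) are read
at the **Youden-optimal threshold** of the cycle's ROC, with **NCH as the
positive class** throughout. ROC curves are built by a threshold sweep
over unique scores with trapezoidal AUC, which equals the Mann–Whitney
pairwise-ordering probability (asserted against a pair-counting oracle).
AUC distributions across the four feature-set models are compared by
one-way ANOVA (no covariate) with Bonferroni-corrected pairwise Welch
tests.

**Stopping rule.** By default the network trains to a loss plateau
(`tol`-based, `max_iter = 500`) rather than stopping on a held-out
validation split. With ~81 training rows per fold, a 10% validation split
holds ~8 samples; validation-based early stopping then triggers after
~20 adam iterations and underfits substantially (per-cycle AUC ~0.86–0.91
versus ~0.99 when trained to plateau on the default synthetic cohort).
Validation early stopping remains available via
`ClassifierConfig(early_stopping=True)`.

Segmentation agreement between two observers is the DICE coefficient
`2|A∩B|/(|A|+|B|)`, reported per lesion with the conventional > 0.7
"excellent agreement" flag and summarized as mean ± sd.

## The synthetic cohort

No patient data accompany the procedure, so the generator produces a
cohort with the statistical structure the analysis assumes: 42 NCH + 49
ACA solid lesions, largest diameters drawn from 14.3 ± 6.0 mm (NCH) and
22.6 ± 7.4 mm (ACA) truncated to [6, 41] mm (out-of-range draws are
redrawn), in 64³ volumes at 1 mm isotropic voxels with lung-parenchyma
background (−800 ± 30 HU). Masks are ellipsoids whose largest semi-axis
is the drawn diameter/2, the other two shrunk by random factors in
[0.7, 1].

Intra-lesion texture is a Gaussian random field: white noise smoothed
with a Gaussian kernel at the class's correlation length and rescaled to
an 80 HU amplitude — the correlation length is the single heterogeneity
knob, **1.5 mm for NCH versus 6 mm for ACA**. NCH lesions additionally
get a random blob partition of the mask (argmax over three smoothed
fields at 6 mm scale) assigning component means of 40 HU (soft tissue),
−80 HU (fat-like) and 80 HU (cartilage-like), reflecting the
mixed-tissue composition that makes hamartomas heterogeneous; ACA
interiors are single-component soft tissue (35 HU). Voxel noise is 5 HU.
Every masked voxel is clipped strictly below the 120 HU calcification
bound — a lesion with calcification would not be in this cohort. Field
amplitude and correlation lengths were calibrated once so that the pooled
GLCM contrast, entropy and dissimilarity have higher NCH-class means — the
direction of effect the analysis is designed to detect — and then frozen.

Per-lesion seeds derive from the cohort seed via `SeedSequence`, so a
cohort is reproducible byte-for-byte while lesions stay independent.

**What the phantom does not emulate:** scanner reconstruction kernels,
dose and multi-scanner effects, anisotropic voxels, ground-glass or
cavitating lesions, pleural contact or vasculature, and any calibrated
relationship between the two classes' absolute feature values and those
of real tumors. Passing the end-to-end checks therefore demonstrates that
the pipeline detects the *kind* of heterogeneity contrast the two classes
are reported to show, at the cohort scale reported — not clinical
performance on real CT.

## Problem sizes and numerical notes

The repeated-CV evaluation defaults to 10 folds × 100 cycles; the
packaged end-to-end checks and the reproduction script run 20 cycles per
feature set, which is enough for stable mean ± sd summaries on the 91
lesion cohort. The label-permutation null redraws the permutation every
cycle, so its mean AUC averages over permutations rather than conditioning
on one. Ties in the maximum-area slice and in ROC thresholds break
deterministically (smallest index / stable sort); all pipeline stages are
deterministic given their seeds, which the byte-identity test asserts.

## Known limitations

- The sigmoid-fit target and the LBP "histogram mean" are artifact
  conventions for under-specified definitions; both are recorded here and
  flagged in the API docs.
- The t-tests assume approximate normality of feature values; several
  texture features are bounded and skewed at small lesion sizes.
- At the default 8-level quantization very small lesions (max-area slice
  under ~3×3 pixels) cannot support LBP and raise informative errors
  rather than returning padded values.
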