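# Methods

This note documents the models and procedures implemented in
`bct_texture`, the choices made where the underlying study protocol left
the design open, and what the synthetic phantoms can and cannot
establish about real breast-CT data.

## The problem

Breast density — the relative amount of fibroglandular versus fatty
tissue — is graded on a four-level ordinal scale (*a* almost entirely
fatty … *d* extremely dense). On dedicated breast CT, density grading is
currently done by eye and suffers from inter-reader variability. The
pipeline implemented here asks whether quantitative texture features of
the coronal image stack can grade density objectively: extract 19
first- and second-order texture features per examination, screen them
for discriminative power and redundancy, and classify the grade with
multinomial logistic regression. A reader-agreement module supplies the
statistics needed to compare the automated grading with human readers.

## Synthetic phantoms

Real breast-CT volumes are not redistributable, so the `phantom` module
generates surrogate examinations with known ground truth. Each
examination is a stack of `n_slices = 50` coronal slices of 256 × 256
pixels at 0.3 mm isotropic spacing — matching the soft-kernel
reconstruction grid of dedicated spiral breast CT and the convention of
analysing 50 representative coronal images per examination (25 per
breast, pooled into one analysis).

Per slice, the breast cross-section is a disk covering 90 % of the
half-width. The gland/fat partition inside it is made by smoothing a
standard-normal random field with a Gaussian kernel
(`correlation_length_px = 10`, i.e. 3 mm) and thresholding it at the
`1 − gland_fraction` quantile of the within-support values. This
construction was chosen because it produces connected glandular regions
interleaved with fat at an exactly controllable area fraction — a
caricature of the fatty septae that make breast-CT texture informative.
Gland pixels take intensity 70, fat pixels 30 (arbitrary units — the
feature normalisation is affine-invariant, so only their order
matters), plus independent Gaussian noise with sd 5. The pooled
within-breast histogram is therefore bimodal with the peak balance set
by the density class, reproducing the qualitative histogram shapes seen
on real stacks.

Gland volume fractions per class default to a: 0.10, b: 0.35, c: 0.60,
d: 0.85. These anchors are invented plumbing chosen to straddle the
four-level scale symmetrically; only their strict increase a → d is
load-bearing (it drives the monotone skewness behaviour and the
classifier separability). For a two-point intensity mixture with gland
fraction *p*, histogram skewness is `(1 − 2p)/√(p(1−p))`, strictly
decreasing in *p* — so class-mean skewness must fall from *a* to *d*,
which is the sign observed on real data (strong negative rank
correlation of skewness with density).

What the phantom does **not** model: X-ray physics, reconstruction
kernels and artefacts, skin and chest-wall anatomy, left/right breast
differences, lesions and calcifications, and the heavy-tailed
between-patient variability of real parenchyma. Consequently, phantom
results validate the *machinery* (feature math, selection logic, model
fitting) and the *direction* of effects, not the absolute feature
magnitudes or the clinically achievable accuracy. On phantoms the four
classes are nearly noiseless in gland fraction, so classifier accuracy
is far higher than on patients; it is asserted only as "well above
chance".

## ROI handling

The region of interest is a single polygon (freehand in clinical use;
the support-disk outline for phantoms). Pixel membership is decided at
pixel centers by the even-odd rule with half-open boundary semantics
(centers on a lower edge are inside, on an upper edge outside), which
makes rasterisation exactly testable by enumeration. The skin margin —
nominally 5 mm, to keep subcutaneous fat out of the statistics — is
formalised as morphological erosion by a disk of
`round(margin_mm / pixel_spacing_mm)` pixels (17 px at 0.3 mm). The
eroded mask is propagated unchanged to every analysed slice; slices to
exclude (e.g. showing chest-wall structures) are listed explicitly
rather than detected automatically.

## Grey-level normalisation and quantisation

Texture features are computed on quantised grey levels: masked values
pooled over all analysed slices are clipped to mean ± 3 sd and binned
uniformly onto `1..N_g` with `N_g = 64`. The μ ± 3σ window is the
standard choice in the texture-analysis literature this feature set
comes from; it makes all 19 features invariant to affine intensity
rescaling (scanner calibration, arbitrary units). `N_g` is configurable;
the oracle tests use small `N_g` where brute-force enumeration is
feasible. A zero-variance region maps to level 1 everywhere.

## The 19 features

*First order* (pooled level histogram): variance, skewness, kurtosis,
entropy. Population (1/N) moments; kurtosis is **excess** kurtosis
(normal = 0); entropy is in bits. A constant region returns 0 for all
four by convention.

*GLCM*: co-occurrence counts at distance 1 along the four in-plane
directions (0°, 45°, 90°, 135°), counted only where both pixels are
masked, accumulated over slices and directions, symmetrised, then
normalised. Features: contrast Σ(i−j)²P, energy ΣP², homogeneity
ΣP/(1+|i−j|), correlation Σ(i−μx)(j−μy)P/(σxσy) with correlation := 1
when a single level makes the marginals degenerate.

*GLRLM*: maximal runs of equal level along the same four directions; an
unmasked pixel terminates a run; counts accumulate over slices and
directions. `N_p` is the pooled masked pixel count times the number of
directions, so run lengths always conserve pixels
(Σⱼ j·p(i,j) = N_p). The eleven run statistics (SRE, LRE, GLN, RLN, RP,
LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE) use the standard emphasis
formulas with level index i and length index j.

Accumulating counts (rather than averaging per-direction feature
values) handles sparse masks gracefully; per-direction averaging is
available as a config option. Histograms and matrices are pooled over
the full stack **before** any feature is computed, giving one value per
examination and avoiding per-slice pseudo-replication.

## Feature selection

1. **ANOVA screen.** One-way ANOVA across the four classes plus all six
   pairwise pooled-variance t-tests (Welch optional), Bonferroni
   adjusted (× 6, capped at 1). A feature survives only if every pair
   differs at adjusted p < 0.05 — a deliberately strict rule: a density
   feature useless for *some* adjacent pair is useless as a grader.
2. **Rank-correlation screen.** Spearman rho against the ordinal grade
   (a=1…d=4), average ranks for ties, t-approximation p (exact
   permutation enumeration for n ≤ 10). Survivors need p < 0.05 and
   |rho| > 0.50, i.e. at least "moderate" on the strength bands used
   throughout (absent ≤ 0.10 < weak ≤ 0.50 < moderate ≤ 0.80 < strong).
3. **Redundancy rejection.** Pairwise Spearman matrix among the ANOVA
   survivors; average-linkage clustering on 1 − |rho| for reporting.
   Among surviving pairs with |rho| ≥ 0.80 (strongest pair first), the
   member with the larger mean absolute correlation to the other
   candidates is rejected as the less independent one; ties break
   toward keeping the stronger density correlate, then alphabetically.
   The independence score formalises the narrative reasoning by which
   grey-level nonuniformity (less entangled) is preferred over
   run-length nonuniformity (stronger density correlation but entangled
   with the first-order block). Rejected features are never reinstated,
   and every rejection carries a machine-readable reason
   (`anova_fail`, `nonsignificant_rho`, `redundant_with:<name>`).

No multiplicity correction is applied across the 19 features at step 2
(matching the original protocol, which corrected only within the
post-hoc family).

On phantom cohorts the cascade behaves differently from patient data in
one expected way: a single latent variable (gland fraction) drives all
19 features, so almost every surviving pair exceeds the 0.80 redundancy
bound and step 3 collapses the set to a minimal, essentially
interchangeable pair. The patient-data outcome — skewness plus
grey-level nonuniformity — is therefore exercised through the
worked-example replay on the published screening statistics rather than
through phantoms.

## Classifier

Softmax (multinomial logistic) regression of grade on standardized
features, reference class *a*: `P(k|x) ∝ exp(b_k + w_k·x)` with the
reference score fixed at 0. Coefficients maximise the log-likelihood
with a small L2 ridge (1e-4 on slopes, intercepts unpenalised) that
keeps separable phantom data finite; the penalised objective is
strictly convex, so the fit is deterministic (the seed argument exists
only for interface symmetry). Optimisation is L-BFGS with analytic
gradients, gradient tolerance 1e-6, at most 500 iterations;
non-convergence is flagged with the final gradient norm rather than
raised. Constant features are dropped with a warning.

Evaluation: per-class stratified 70/30 split (ceil-rounding sends the
remainder to train), confusion matrix with rows = true class, per-class
recall and overall accuracy in percent (raw plus one-decimal rounding).
Training- and test-set accuracies are reported separately and labelled.
Which features enter is configurable: all 19, the ANOVA survivors
(default — the set in play when the regression is run in the original
protocol), or the final retained set.

## Reader agreement

Percent agreement is the confusion-matrix trace over the total (raw and
integer-rounded). Cohen's κ uses the marginal-product chance term;
κ is undefined (NaN, flagged) when both raters use a single category.
Verbal bands follow Landis–Koch. The intraclass correlation is
ICC(2,1) — two-way random effects, absolute agreement, single rater —
computed from the mean-square decomposition with the standard F-based
95 % interval; the variant is recorded in the output because the
choice materially affects the value. The per-feature inter-reader
coefficient of variation is computed per item as 100·sd/mean across
readers (sample sd), then averaged over items; the sign of the mean is
carried (so predominantly negative features such as skewness report
negative CV), and zero-mean items are excluded and flagged.

## Worked-example reference tables

`reference_tables.py` transcribes the published summary tables (test-set
confusion matrix, the two reader matrices, worst-case adjusted p-values,
density correlations). They serve as fixtures: re-deriving the printed
per-class recalls, agreement percentages, candidate count and retained
feature pair from them exercises the same code paths as a fresh
analysis. Two caveats are inherent to the printed tables and are
documented in code: the class-c recall computes to 75.6 % against a
printed 75.5 % (presumably a transcription or rounding slip in print),
and the direct-formula kappas are 0.866/0.844 against printed 0.86/0.83;
the package reports unrounded values. The inter-feature correlation
matrix used in the selection replay is a synthetic completion — only a
few entries were reported numerically, the rest are set to zero — and
only the relative entanglement of GLN vs RLN is load-bearing.

## Problem sizes and numerical conventions

Default texture parameters: `N_g = 64`, GLCM distance 1, four in-plane
directions, count accumulation. Degenerate-input conventions (all
chosen to give fixed, testable values instead of NaNs): σ = 0 →
variance/skewness/kurtosis/entropy = 0; single-level GLCM → correlation
= 1; constant Spearman feature → rho 0, p 1, flagged. Phantom cohorts
used by the test suite and the acceptance script are 10 and 50
examinations per class (40 and 200 stacks) at the full default geometry
— the larger one matches the original cohort size of 50 patients per
density level. Tiny oracle fixtures (8 × 8 slices, N_g ≤ 4) are sized so
a loop-based brute-force reimplementation stays exact.

## Known limitations

- The phantom's four classes are much better separated than real
  patients; phantom classifier accuracy is an upper bound of machinery
  correctness, not a clinical estimate.
- Absolute feature magnitudes depend on `N_g` and the normalisation
  window and are not comparable across parameter settings (or with
  values computed by other toolkits using different conventions).
- The GLCM/GLRLM direction set and aggregation are configurable but the
  defaults are a convention, not a protocol reconstruction — the
  original study did not state its offsets.
- Single-polygon ROI propagation assumes the breast outline is stable
  across slices; no registration is attempted.
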