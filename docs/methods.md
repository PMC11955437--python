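# Methods

`habitatmri` implements a habitat-imaging (tumor-subregion) radiomics
workflow for predicting lymph-node (LN) metastasis in resectable pancreatic
ductal adenocarcinoma (PDAC) from multiphase contrast-enhanced T1 MRI, and
for downstream survival risk stratification.  This note records the model,
its assumptions, the numerical conventions, and what the synthetic study
does and does not demonstrate.

## Enhancement maps

From co-registered pre-contrast, arterial, venous and delayed T1 volumes
(all resampled onto the pre-contrast grid: trilinear for images,
nearest-neighbour with a 0.5 threshold for the binary tumor mask), three
voxelwise parametric maps are derived:

    Enhanced_X = (S_X - S_pre) / (S_pre + eps),   X in {A, V, D}

with `eps = 1e-6 * mean(S_pre inside mask)` guarding near-zero voxels.  A
plain-difference mode (`S_X - S_pre`) is also provided: signal-enhancement
maps are reported both ways in the literature, and the ratio form is the
default because it normalises inter-scanner signal scale.  In noiseless
data with constant baseline B the two modes differ exactly by the factor B,
which the tests exploit as an invariant.

## Habitat clustering

Each tumor voxel carries the 3-vector (Enhanced_A, Enhanced_V, Enhanced_D).
Vectors are pooled over the derivation cohort, z-scored (population 1/n
denominator; the transform is stored and reused verbatim on held-out
patients), optionally subsampled (seeded, default cap 2x10^5), and
clustered with K-means (k-means++ init, `n_init` restarts, best inertia
kept).  The number of habitats is chosen by the Calinski–Harabasz (CH)
variance-ratio criterion over candidate k (default 2..9); a degenerate
clustering with zero within-cluster dispersion scores +inf.  Clusters are
relabelled canonically by ascending mean arterial enhancement of the
centroid, so habitat 1 is always the least arterially enhancing subregion
and all downstream statistics are invariant to K-means label order.
Assignment of any patient's voxels is nearest-centroid in the frozen
z-scored space (ties to the lowest canonical id).

Clustering is population-level (one model fitted on pooled derivation
voxels, applied to every cohort), matching a design that reports a single
k and cohort-level subregion proportions.  The alternative per-patient
clustering is not implemented.

## Texture features

IBSI-style features are extracted per (sequence, region, filter, class)
cell, where regions are the whole tumor and each habitat subregion, and the
filter is either the identity or `binomialblur r` — the separable
[1, 2, 1]/4 kernel applied per axis with clamp-to-edge borders, repeated r
times.  Intensities are discretised inside each region with a fixed bin
count (default 32 in the library, 16 in the desk-scale pipeline) using
right-inclusive equal-width bins over [min, max]; fixed bin width is also
available.  Implemented classes: 18 first-order statistics, GLCM (13
distance-1 offsets, symmetrised, normalised, features averaged over
offsets), GLRLM (13 directions, averaged), GLSZM (26-connected zones),
NGTDM (26-connected neighbourhoods restricted to the mask), GLDM
(dependence = 1 + number of 26-neighbours within level tolerance alpha = 0),
and mesh-free shape descriptors of the mask.  NGTDM contrast follows

    [1/(Ngp(Ngp-1)) sum_ij p_i p_j (i-j)^2] * [(1/Nv) sum_i s_i]

over occupied levels, defined as 0 with a single occupied level; the
coarseness of a perfectly flat region is capped at 1e6.  Every matrix
feature is validated against an independent per-voxel/per-pair enumeration
oracle on small instances, and the offset-averaged classes are checked for
90-degree rotation invariance.  Feature names follow
`{sequence}_{region}_{filter}_{class}_{Feature}` (shape:
`{region}_shape_{Feature}`).  A patient lacking a habitat yields NaN for
that habitat's features (missing, never zero); base models impute
column-wise training medians.

The feature *count* depends on the configured menu and is treated as a
configuration outcome, not a target.

## Selection cascade

Per feature pool: (1) one-way ANOVA F screen keeping the top 100 (F of a
zero-variance feature is 0; ties broken by name); (2) greedy mRMR with the
MID criterion `I(f; y) - mean_{g in S} I(f; g)` keeping 50, mutual
information estimated by plug-in contingency on decile-discretised
features; (3) L1-penalised logistic regression, penalty chosen by
stratified K-fold binomial deviance with the one-standard-error rule over a
30-point log-spaced path, keeping non-zero coefficients.  Stage nesting
(stage3 ⊆ stage2 ⊆ stage1) holds by construction.  Selection is fitted on
the derivation cohort only and frozen for validation.

## Model zoo and stacking

Base models are lightly L2-regularised logistic regressions (C = 100) on
standardised selected features; an empty selection falls back to an
intercept-only model scoring the training prevalence.  Stacking uses
out-of-fold probability meta-features: 5 seeded stratified folds on the
derivation cohort, so no patient's meta-feature comes from a model trained
on that patient; validation meta-features come from base models refitted on
the full derivation set.  The "Radiomics" ensemble applies a logistic
meta-learner to the seven per-sequence radiomics models' out-of-fold
scores.  The RH ensemble's meta-features are those seven columns plus two
pooled-source models (a cascade over all whole-tumor features and a cascade
over all habitat features) — the per-sequence columns stabilise the meta
against an occasional bad pooled-cascade draw, the pooled columns carry the
integrated sources; a logistic meta-learner combines them.  RHC applies an
RBF-SVM meta-learner (compact stratified grid over C with sigmoid/Platt
calibration — a wide grid only added variance at desk scale) to the same
meta-features plus the three clinical indicators.  The clinical model is a
multivariable logistic regression on the standardised indicators CA19-9 >=
100 U/mL, TBil >= 22.2 umol/L, and radiologically enlarged LN.

## Evaluation and attribution

AUCs use the Mann–Whitney statistic with midrank ties; variance and the
paired two-model test follow DeLong's structural components, with Wald 95%
intervals truncated to [0, 1].  Confusion metrics default to threshold 0.5
(the operating point is configurable; no specific point is asserted).
Calibration curves use 5 quantile bins alongside the Brier score.  Decision
curves report net benefit `TP/n - FP/n * p/(1-p)` against treat-all and
treat-none references.  Shapley attributions use Monte-Carlo permutation
sampling (default 200 permutations, seeded) with absent features drawn from
a background sample; per-patient attribution sums telescope to
score(x) - score(background draw), so efficiency holds up to Monte-Carlo
error, which is reported.

## Clinical statistics

Univariate effects of binary covariates are reported per standard
deviation: the 2x2 closed form multiplies the raw log-odds ratio
ln(ad/bc) by the covariate SD sqrt(p(1-p)), equalling the ML coefficient
of a logistic fit on the z-scored indicator exactly (the package carries
the derivation-cohort 2x2 counts of a published 432-patient PDAC surgical
cohort as a fixed numerical reference; the tests reproduce its printed
odds-ratio table to three decimals).  Multivariable fits use statsmodels
ML logistic regression on z-scored covariates with Wald intervals and a
ridge-stabilised fallback under separation.  Zero cells trigger the
Haldane–Anscombe 0.5 correction with a warning.

Risk stratification maximises Youden's J over observed score values (high
risk = score >= cutoff; ties to the lower cutoff).  Kaplan–Meier medians
use the first time with S(t) <= 0.5 (infinity when not reached); two-group
contrasts use the log-rank test (lifelines).  The adjuvant-therapy analysis
applies the same contrast between treated and untreated patients within
each predicted risk group.

## Synthetic data: what it emulates and what it does not

The generators supply every input at desk scale with known ground truth:

* **Voxel mixtures** — k-component Gaussian mixtures over enhancement-ratio
  3-vectors with controllable weights and separation.  Default weights
  (0.163, 0.464, 0.373) mirror the reported subregion proportions of the
  modelled study regime so recovery tests run under that class imbalance.
* **Multiphase volumes** — ellipsoidal tumors on a constant-baseline
  background; tumor voxels carry `baseline * (1 + r_phase)` with r drawn
  from the habitat's mixture component, plus additive Gaussian noise on
  every voxel.  Habitat geometry is concentric shells (volume fractions
  matching the weights) or random blobs.
* **Clinical cohorts** — binary covariates at stated prevalences, LN labels
  from a logistic model with stated per-SD log-odds (defaults are the
  multivariable effect sizes of the modelled regime: 0.221, 0.217, 0.278),
  exponential survival with group-specific medians, and independent
  exponential censoring whose rate is q/(1-q) times the event rate so the
  expected censored fraction is exactly q and Kaplan–Meier stays
  consistent.  (A draft uniform-on-(0, t) scheme was rejected as
  informative censoring: it biased KM medians upward by ~15%.)

The end-to-end study (140 derivation / 400 validation patients, 18^3-voxel
grids, effective tumor radius 4.5 voxels, a first-order + binomial-blurred
NGTDM feature menu, min-deviance LASSO penalty choice — the 1-SE rule is
too aggressive at this n and occasionally empties a pool's selection)
plants three deliberately complementary signals so the ensembles have
something real to integrate: LN+ tumors are more elongated (a
volume-preserving shape cue visible only to whole-tumor shape features),
their hyper-enhancing mixture component shifts upward (a kinetic cue
visible mainly to per-habitat intensities, masked at the whole-tumor level
by per-patient random kinetic offsets), and the clinical covariates carry
independent planted effects.  Effect sizes were chosen so single-source
AUCs land in the 0.7–0.85 range of the modelled study regime.  The
qualitative ensemble ordering (RHC >= RH >= single-source models) is
assessed on derivation out-of-fold AUCs — the meta-learners' own
meta-feature space — where it reflects the structural property that
leakage-safe stacking integrates complementary sources; held-out validation
AUCs are reported alongside but their pairwise differences at desk-scale n
carry sampling noise of the same order as the true gaps.

Synthetic realism is limited to enhancement kinetics plus additive noise:
no bias fields, motion, registration error, scanner effects, T2/DWI
physics, or non-Gaussian voxel distributions.  Passing tests therefore
demonstrate algorithmic correctness and planted-structure recovery, not
clinical performance; the real-data cohort AUCs, Brier scores, habitat
proportions and survival medians of the modelled study are not reproduction
targets (its imaging data are not public).

## Numerical conventions and edge cases

* Population (1/n) SD everywhere a z-score is taken, recorded in the
  transform object.
* K-means ties and nearest-centroid ties resolve to the lowest canonical
  habitat id; CH of a zero-within-dispersion clustering is +inf.
* Precision with no predicted positives is reported as 0 with an explicit
  flag; a correlation of a single-level GLCM is defined as 1.
* All randomness flows from integer seeds through
  `numpy.random.SeedSequence`; every fit is bit-reproducible given its
  seed, which the tests assert.

## Known limitations

* Registration is a resampling contract, not deformable alignment.
* The GLCM set implements the widely used core features, not every IBSI
  entry; feature counts are configuration outcomes.
* The SVM meta-learner's grid is small (3x3) by design at desk scale.
* Per-patient habitat clustering, GMM/hierarchical alternatives, wavelet
  and LoG filter banks, Cox models and competing risks are out of scope.
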