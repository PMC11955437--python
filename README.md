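# habitatmri

Habitat (tumor-subregion) imaging and radiomics for predicting lymph-node
(LN) metastasis in resectable pancreatic ductal adenocarcinoma (PDAC) from
multiphase contrast-enhanced MRI, with survival-based risk stratification.

Preoperative LN status drives surgical planning and prognosis in PDAC, but
whole-tumor radiomics averages away intratumoral heterogeneity (ITH).
Habitat imaging instead clusters tumor voxels by their contrast-enhancement
kinetics into subregions ("habitats") and extracts texture features per
subregion.  This package provides that pipeline end to end, for
methodologists who want a tested, reproducible implementation they can run
on synthetic data with known ground truth or point at their own NIfTI
cohorts:

* **Enhancement maps** — `Enhanced_X = (S_X − S_pre)/(S_pre + ε)` for the
  arterial, venous and delayed phases (difference mode available), after
  resampling all phases onto the pre-contrast grid.
* **Habitat clustering** — K-means on pooled z-scored voxel 3-vectors with
  the number of habitats k chosen by the Calinski–Harabasz criterion
  `CH(k) = [B/(k−1)]/[W/(n−k)]`, canonical habitat order by ascending
  arterial enhancement.
* **Texture features** — IBSI-style first-order, GLCM, GLRLM, GLSZM,
  NGTDM, GLDM and shape features per whole tumor and per habitat, with the
  binomial-blur ([1,2,1]/4) filter family.
* **Selection cascade** — ANOVA F screen (top 100) → mRMR with the MID
  criterion `I(f;y) − mean_g I(f;g)` (top 50) → L1 logistic regression with
  cross-validated penalty (1-SE rule).
* **Model zoo** — per-sequence logistic models, pooled radiomics/habitat
  models, an out-of-fold stacked RH ensemble (logistic meta-learner) and an
  RHC ensemble (RBF-SVM meta-learner with Platt calibration) adding the
  clinical covariates CA19-9 ≥ 100 U/mL, TBil ≥ 22.2 μmol/L and
  radiologically enlarged LN.
* **Evaluation & survival** — AUC with DeLong variance and the paired
  DeLong test, confusion/calibration/decision-curve metrics, Monte-Carlo
  Shapley attributions, per-SD odds ratios (closed 2×2 form ≡ IRLS),
  Youden-cutoff risk groups, Kaplan–Meier + log-rank contrasts and the
  adjuvant-therapy subgroup analysis.

A synthetic-data module generates every input the pipeline needs — voxel
mixtures, multiphase volumes with planted habitats, and clinical/survival
cohorts with planted effect sizes — so the whole analysis is testable
without patient data.  See `docs/methods.md` for the model details and
design choices.

## Worked example

```python
>>> from habitatmri.survival import reference_univariate_results
>>> print(reference_univariate_results().round(3))
              coefficient     or  ci_low  ci_high      p
covariate
sex_male            0.105  1.111   0.918    1.345  0.280
diabetes            0.048  1.049   0.868    1.269  0.621
hypertension       -0.029  0.972   0.803    1.176  0.767
tbil_high           0.296  1.344   1.111    1.627  0.002
ca199_high          0.293  1.341   1.104    1.628  0.003
enlarged_ln         0.320  1.377   1.137    1.668  0.001
```

These are per-SD univariate odds ratios computed from the embedded
derivation-cohort 2×2 counts of a 432-patient PDAC surgical cohort: e.g. a
one-SD increment in the enlarged-LN indicator multiplies the odds of LN
metastasis by 1.377 (95% CI 1.137–1.668, p = 0.001), while sex, diabetes
and hypertension show no association.  The same numbers fall out of a full
IRLS logistic fit on the z-scored indicator — the closed form and the ML
fit agree to 1e-6, which the test suite asserts.

Running the full synthetic study:

```python
>>> from habitatmri.pipeline import RunConfig, run_end_to_end
>>> res = run_end_to_end(RunConfig(seed=1))   # ~35 s on one CPU
>>> res.habitat_model.k_
3
>>> res.aucs.round(3).sort_values(ascending=False)
RHC                 0.855
RH                  0.823
Radiomics           0.818
Habitat             0.779
Original_habitat    0.759
Enhanced_habitat    0.733
Clinical            0.708
dtype: float64
>>> res.survival_results["rfs"].medians, res.survival_results["rfs"].p_value
({'high': 386.3, 'low': 595.2}, 0.0002)
```

The Calinski–Harabasz criterion selects k = 3 habitats on the pooled voxel
space; on the 400 held-out synthetic patients the stacked RHC model
discriminates best (AUC 0.855), RH beats every single-source model, the
clinical model is weakest (0.708), and the RHC-defined high-risk group has
a significantly shorter median recurrence-free survival (386 vs 595 days,
log-rank p = 2e-4) — the qualitative pattern the method is designed to
produce when imaging, habitat and clinical sources each carry partial,
complementary signal.

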