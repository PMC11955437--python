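"""Model zoo: per-source logistic base models and stacked RH/RHC ensembles.

Each base model (per-sequence radiomics, per-sequence habitat, combined
habitat, clinical) is a lightly L2-regularised logistic regression on its
selected, standardised features.  Ensembles are stacked: base models
produce out-of-fold probability meta-features on the derivation cohort
(5 stratified folds, seeded), a meta-learner is fitted on those, and base
models are refitted on the full derivation set to score validation
cohorts — so no patient's meta-feature ever comes from a model trained on
that patient.

* RH — Radiomics + Habitat meta-features, logistic meta-learner.
* RHC — Radiomics + Habitat + Clinical meta-features, RBF-SVM meta-learner
  with a small stratified grid search and Platt-style sigmoid calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted


class LogisticScorer(BaseEstimator, ClassifierMixin):
    """Logistic regression on a fixed feature subset with frozen scaling.

    Falls back to an intercept-only model (constant training-prevalence
    score) when the feature list is empty — the contract for a cascade
    that selected nothing.
    """

    def __init__(self, features: list[str] | None = None, C: float = 100.0,
                 impute_median: bool = True):
        self.features = features
        self.C = C
        self.impute_median = impute_median

    def _matrix(self, X: pd.DataFrame, fit: bool) -> np.ndarray:
        cols = list(self.features) if self.features else list(X.columns)
        A = X[cols].to_numpy(dtype=np.float64)
        if self.impute_median:
            if fit:
                med = np.nanmedian(A, axis=0)
                self.medians_ = np.where(np.isfinite(med), med, 0.0)
            A = np.where(np.isnan(A), self.medians_, A)
        return A

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.features is not None and len(self.features) == 0:
            self.prevalence_ = float(np.mean(y))
            self.pipeline_ = None
            return self
        A = self._matrix(X, fit=True)
        self.pipeline_ = Pipeline([
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(C=self.C, max_iter=2000)),
        ]).fit(A, y)
        self.coef_ = self.pipeline_.named_steps["logit"].coef_.ravel()
        self.intercept_ = float(self.pipeline_.named_steps["logit"].intercept_[0])
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "classes_")
        if self.pipeline_ is None:
            p = np.full(len(X), self.prevalence_)
            return np.column_stack([1 - p, p])
        return self.pipeline_.predict_proba(self._matrix(X, fit=False))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score_samples(self, X) -> np.ndarray:
        """Probability of the positive class (LN metastasis)."""
        return self.predict_proba(X)[:, 1]


def fit_base_model(X: pd.DataFrame, y, features: list[str], C: float = 100.0
                   ) -> LogisticScorer:
    """Fit one named base model on its selected feature subset."""
    return LogisticScorer(features=features, C=C).fit(X, y)


def stratified_folds(y, n_splits: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment; reseeds (logged) if a fold lacks a class."""
    y = np.asarray(y)
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed + attempt)
        assign = np.zeros(len(y), dtype=int)
        ok = True
        for i, (tr, _) in enumerate(skf.split(np.zeros(len(y)), y)):
            assign[np.setdiff1d(np.arange(len(y)), tr)] = i
            if len(np.unique(y[tr])) < 2:
                ok = False
        if ok:
            if attempt:
                warnings.warn(f"refolded with seed offset {attempt} to keep both "
                              "classes in every training fold")
            return assign
    raise ValueError("could not build stratified folds with both classes")


def out_of_fold_scores(models: dict[str, BaseEstimator], X: pd.DataFrame, y,
                       n_splits: int = 5, seed: int = 0
                       ) -> tuple[pd.DataFrame, np.ndarray]:
    """Out-of-fold positive-class scores for each base model.

    Every patient is scored exactly once per model, by the clone trained on
    the folds that exclude it.  Returns (score matrix, fold assignment).
    """
    y = np.asarray(y)
    folds = stratified_folds(y, n_splits=n_splits, seed=seed)
    scores = pd.DataFrame(index=X.index, columns=list(models), dtype=float)
    for fold in range(n_splits):
        tr, te = folds != fold, folds == fold
        for name, model in models.items():
            m = clone(model).fit(X.loc[tr], y[tr])
            scores.loc[te, name] = m.predict_proba(X.loc[te])[:, 1]
    return scores, folds


def _svm_meta(seed: int):
    # compact grid: meta-feature spaces are low-dimensional and already
    # standardised, so a wide hyperparameter search only adds variance
    grid = {"C": [1.0, 10.0], "gamma": ["scale"]}
    search = GridSearchCV(SVC(kernel="rbf", random_state=seed), grid,
                          scoring="roc_auc",
                          cv=StratifiedKFold(3, shuffle=True, random_state=seed))
    return CalibratedClassifierCV(search, method="sigmoid",
                                  cv=StratifiedKFold(5, shuffle=True, random_state=seed))


class StackedEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Out-of-fold stacking of named base models with an LR or SVM meta-learner.

    Parameters
    ----------
    base_models : dict name -> unfitted estimator with predict_proba.
    meta : "lr" for a logistic meta-learner (RH), "svm" for an RBF SVM with
        grid search and sigmoid (Platt) calibration (RHC).
    extra_features : optional column names of X passed through to the
        meta-learner alongside the base-model scores (the clinical
        covariates of the RHC stack).
    """

    def __init__(self, base_models: dict | None = None, meta: str = "lr",
                 n_splits: int = 5, extra_features: list[str] | None = None,
                 random_state: int = 0):
        self.base_models = base_models
        self.meta = meta
        self.n_splits = n_splits
        self.extra_features = extra_features
        self.random_state = random_state

    def _meta_matrix(self, scores: pd.DataFrame, X: pd.DataFrame) -> pd.DataFrame:
        if self.extra_features:
            return pd.concat([scores, X[self.extra_features]], axis=1)
        return scores

    def fit(self, X: pd.DataFrame, y):
        if self.meta not in ("lr", "svm"):
            raise ValueError("meta must be 'lr' or 'svm'")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        oof, self.folds_ = out_of_fold_scores(self.base_models, X, y,
                                              n_splits=self.n_splits,
                                              seed=self.random_state)
        meta_X = self._meta_matrix(oof, X)
        constant = meta_X.std(axis=0) == 0
        if constant.any():
            warnings.warn(f"dropping constant meta-feature(s): "
                          f"{list(meta_X.columns[constant])}")
            meta_X = meta_X.loc[:, ~constant]
        self.meta_columns_ = list(meta_X.columns)
        self.oof_scores_ = oof
        if self.meta == "lr":
            learner = Pipeline([("scale", StandardScaler()),
                                ("logit", LogisticRegression(max_iter=2000))])
        else:
            learner = Pipeline([("scale", StandardScaler()),
                                ("svm", _svm_meta(self.random_state))])
        self.meta_model_ = learner.fit(meta_X.to_numpy(dtype=np.float64), y)
        self.fitted_bases_ = {name: clone(m).fit(X, y)
                              for name, m in self.base_models.items()}
        return self

    def _base_scores(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {name: m.predict_proba(X)[:, 1] for name, m in self.fitted_bases_.items()},
            index=X.index)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "meta_model_")
        meta_X = self._meta_matrix(self._base_scores(X), X)[self.meta_columns_]
        return self.meta_model_.predict_proba(meta_X.to_numpy(dtype=np.float64))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


CLINICAL_COVARIATES = ("ca199_high", "tbil_high", "enlarged_ln")


def fit_clinical_model(cohort: pd.DataFrame, label_col: str = "ln_metastasis",
                       covariates=CLINICAL_COVARIATES) -> LogisticScorer:
    """Multivariable logistic model on the standardised clinical indicators
    (CA19-9 >= 100 U/mL, TBil >= 22.2 umol/L, radiologically enlarged LN)."""
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ValueError(f"missing clinical covariate(s): {missing}")
    return LogisticScorer(features=list(covariates), C=1e6).fit(
        cohort, cohort[label_col].to_numpy())


@dataclass
class PredictionSet:
    """Per-cohort, per-model positive-class scores."""

    scores: dict  # cohort name -> DataFrame (patients x models)

    def frame(self, cohort: str) -> pd.DataFrame:
        return self.scores[cohort]
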