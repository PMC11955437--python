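"""Three-stage feature-selection cascade: F-test screen, mRMR, LASSO.

The cascade mirrors the standard radiomics-signature workflow: a univariate
one-way ANOVA F screen keeps the top 100 features, greedy minimum-redundancy
maximum-relevance (mRMR, MID variant) keeps 50, and an L1-penalised logistic
regression with cross-validated penalty (one-standard-error rule) keeps the
features with non-zero coefficients.  Each stage is a scikit-learn selector
(``fit``/``transform``/``get_support``) so the cascade composes as a
Pipeline; :class:`CascadeSelector` bundles the three and records a
:class:`SelectionTrace` with per-stage rankings and statistics.

Mutual information for mRMR is estimated on features discretised into
deciles, with the MID (difference) criterion
``I(f; y) - (1/|S|) sum_{g in S} I(f; g)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold


@dataclass
class SelectionTrace:
    """Per-stage record of the cascade: names, statistics, settings."""

    stage1: pd.Series | None = None        # F statistic per retained feature (ranked)
    stage2: pd.Series | None = None        # mRMR score per retained feature (pick order)
    stage3: pd.Series | None = None        # LASSO coefficient per retained feature
    chosen_penalty: float | None = None    # C of the selected LASSO fit
    seed: int | None = None
    fold_assignments: np.ndarray | None = None

    @property
    def selected(self) -> list[str]:
        return list(self.stage3.index) if self.stage3 is not None else []


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


class FScreenSelector(SelectorMixin, BaseEstimator):
    """Keep the ``k`` features with the largest one-way ANOVA F statistic.

    For a binary label this is equivalent to ranking by the squared
    two-sample t statistic.  Zero-variance features get F = 0; ties are
    broken by feature-name order.
    """

    def __init__(self, k: int = 100):
        self.k = k

    def fit(self, X, y):
        Xf = _as_frame(X)
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_features_in_ = Xf.shape[1]
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes present")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, _ = f_classif(Xf.to_numpy(dtype=np.float64), y)
        F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)
        names = Xf.columns.to_numpy(dtype=object)
        order = np.lexsort((names, -F))
        keep = order[: min(self.k, len(order))]
        self.scores_ = pd.Series(F[keep], index=names[keep])
        self.support_ = np.zeros(Xf.shape[1], dtype=bool)
        self.support_[keep] = True
        return self

    def _get_support_mask(self):
        return self.support_


def _decile_bins(x: np.ndarray) -> np.ndarray:
    """Discretise a feature into (up to) 10 quantile bins."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, 11)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two small-integer codes.

    Contingency counts via a single bincount over the joint code; zero
    cells contribute nothing.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(np.float64)
    n = joint.sum()
    pa = joint.sum(axis=1) / n
    pb = joint.sum(axis=0) / n
    p = joint / n
    nz = p > 0
    outer = pa[:, None] * pb[None, :]
    return float((p[nz] * np.log(p[nz] / outer[nz])).sum())


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Greedy mRMR with the MID (mutual-information difference) criterion.

    At each step the candidate maximising ``I(f; y) - mean_g I(f; g)`` over
    already-selected g is added; the first pick is the max-relevance
    feature.  Mutual information uses decile-discretised features.
    """

    def __init__(self, k: int = 50):
        self.k = k

    def fit(self, X, y):
        Xf = _as_frame(X)
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_features_in_ = Xf.shape[1]
        y = np.asarray(y)
        names = list(Xf.columns)
        p = len(names)
        k = min(self.k, p)
        if p < self.k:
            warnings.warn(f"only {p} features available for mRMR (k={self.k}); keeping all")
        disc = np.stack([_decile_bins(Xf[c].to_numpy(dtype=np.float64)) for c in names])
        y_code = pd.factorize(y)[0]
        relevance = np.array([mutual_information(disc[i], y_code) for i in range(p)])
        selected: list[int] = []
        scores: list[float] = []
        redundancy_sum = np.zeros(p)
        remaining = set(range(p))
        for _ in range(k):
            if selected:
                crit = relevance - redundancy_sum / len(selected)
            else:
                crit = relevance.copy()
            cand = sorted(remaining)
            best = cand[int(np.argmax(crit[cand]))]
            selected.append(best)
            scores.append(float(crit[best]))
            remaining.discard(best)
            for j in remaining:
                redundancy_sum[j] += mutual_information(disc[j], disc[best])
        self.scores_ = pd.Series(scores, index=[names[i] for i in selected])
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[selected] = True
        return self

    def _get_support_mask(self):
        return self.support_


def _l1_logistic(C: float, seed: int) -> LogisticRegression:
    return LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                              max_iter=2000, random_state=seed)


class LassoLogisticSelector(SelectorMixin, BaseEstimator):
    """L1-penalised logistic selection with CV deviance and the 1-SE rule.

    A path of inverse penalties C is evaluated by stratified K-fold mean
    binomial deviance; the strongest penalty whose mean deviance is within
    one standard error of the minimum is chosen, and features with non-zero
    coefficients in the full-data refit at that penalty are retained.
    Features are standardised internally before fitting.
    """

    def __init__(self, cv: int = 5, n_penalties: int = 30, one_se: bool = True,
                 random_state: int = 0):
        self.cv = cv
        self.n_penalties = n_penalties
        self.one_se = one_se
        self.random_state = random_state

    def fit(self, X, y):
        Xf = _as_frame(X)
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_features_in_ = Xf.shape[1]
        y = np.asarray(y)
        A = Xf.to_numpy(dtype=np.float64)
        mu, sd = A.mean(axis=0), A.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (A - mu) / sd
        n = len(y)
        # C grid from near-total shrinkage to nearly unpenalised
        Cs = np.logspace(-3, 2, self.n_penalties)
        skf = StratifiedKFold(n_splits=self.cv, shuffle=True,
                              random_state=self.random_state)
        folds = list(skf.split(Z, y))
        self.fold_assignments_ = np.zeros(n, dtype=int)
        for i, (_, te) in enumerate(folds):
            self.fold_assignments_[te] = i
        dev = np.zeros((len(Cs), self.cv))
        for ci, C in enumerate(Cs):
            for fi, (tr, te) in enumerate(folds):
                clf = _l1_logistic(C, self.random_state)
                clf.fit(Z[tr], y[tr])
                p = np.clip(clf.predict_proba(Z[te])[:, 1], 1e-12, 1 - 1e-12)
                dev[ci, fi] = -2.0 * np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
        mean_dev = dev.mean(axis=1)
        se_dev = dev.std(axis=1, ddof=1) / np.sqrt(self.cv)
        best = int(np.argmin(mean_dev))
        if self.one_se:
            ok = np.flatnonzero(mean_dev <= mean_dev[best] + se_dev[best])
            chosen = int(ok.min())  # grid ascends in C, so min index = strongest penalty
        else:
            chosen = best
        self.C_ = float(Cs[chosen])
        clf = _l1_logistic(self.C_, self.random_state)
        clf.fit(Z, y)
        coef = clf.coef_.ravel()
        self.support_ = coef != 0
        if not self.support_.any():
            warnings.warn("LASSO selected no features; downstream model will be "
                          "intercept-only")
        self.coefficients_ = pd.Series(coef[self.support_],
                                       index=self.feature_names_in_[self.support_])
        return self

    def _get_support_mask(self):
        return self.support_


class CascadeSelector(BaseEstimator):
    """F-screen -> mRMR -> LASSO cascade with a full :class:`SelectionTrace`.

    Guarantees stage3 ⊆ stage2 ⊆ stage1 ⊆ input features by construction.
    Fit on the derivation cohort only; ``transform`` applies the frozen
    final set to any cohort.
    """

    def __init__(self, k1: int = 100, k2: int = 50, cv: int = 5,
                 one_se: bool = True, random_state: int = 0):
        self.k1 = k1
        self.k2 = k2
        self.cv = cv
        self.one_se = one_se
        self.random_state = random_state

    def fit(self, X, y):
        Xf = _as_frame(X)
        y = np.asarray(y)
        self.f_ = FScreenSelector(k=self.k1).fit(Xf, y)
        X1 = Xf.loc[:, self.f_.support_]
        self.mrmr_ = MRMRSelector(k=self.k2).fit(X1, y)
        X2 = X1.loc[:, self.mrmr_.support_]
        self.lasso_ = LassoLogisticSelector(cv=self.cv, one_se=self.one_se,
                                            random_state=self.random_state).fit(X2, y)
        self.selected_features_ = list(np.asarray(X2.columns)[self.lasso_.support_])
        self.trace_ = SelectionTrace(
            stage1=self.f_.scores_, stage2=self.mrmr_.scores_,
            stage3=self.lasso_.coefficients_, chosen_penalty=self.lasso_.C_,
            seed=self.random_state, fold_assignments=self.lasso_.fold_assignments_)
        return self

    def transform(self, X):
        Xf = _as_frame(X)
        return Xf.loc[:, self.selected_features_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
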