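"""Discrimination, calibration, clinical-utility and attribution metrics.

* AUC with DeLong variance and Wald 95% CI, and the paired DeLong test for
  correlated ROC curves (U-statistic structural components with midranks);
* threshold-based confusion metrics (accuracy, sensitivity, specificity,
  precision, F1);
* Brier score and quantile-binned calibration curves;
* decision-curve analysis: net benefit across threshold probabilities with
  treat-all / treat-none references;
* Monte-Carlo permutation-sampling Shapley attributions for any model that
  exposes a score function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the V10 (per-positive) / V01 (per-negative) structural
    components of the Mann-Whitney statistic with midrank tie handling."""
    labels = np.asarray(labels).astype(int)
    pos = np.asarray(scores, dtype=np.float64)[labels == 1]
    neg = np.asarray(scores, dtype=np.float64)[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need both classes present")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return float(auc), v10, v01


@dataclass
class RocResult:
    auc: float
    variance: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int


def roc_auc_delong(scores, labels, alpha: float = 0.05) -> RocResult:
    """AUC with DeLong variance and a truncated Wald confidence interval."""
    auc, v10, v01 = _delong_components(np.asarray(scores), np.asarray(labels))
    m, n = len(v10), len(v01)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return RocResult(auc=auc, variance=float(var),
                     ci=(max(0.0, auc - half), min(1.0, auc + half)),
                     n_pos=m, n_neg=n)


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided paired DeLong test of AUC_a == AUC_b on the same patients.

    Returns (z, p); identical or rank-equivalent score vectors give z = 0,
    p = 1.
    """
    auc_a, v10_a, v01_a = _delong_components(np.asarray(scores_a), np.asarray(labels))
    auc_b, v10_b, v01_b = _delong_components(np.asarray(scores_b), np.asarray(labels))
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0 or diff == 0:
        return 0.0, 1.0
    z = diff / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    precision_undefined: bool = False


def confusion_metrics(scores, labels, threshold: float = 0.5) -> ConfusionMetrics:
    """Standard confusion metrics at a probability threshold.

    Positive class is LN metastasis; ``predicted positive`` means
    score >= threshold.  With no predicted positives the precision is
    undefined and reported as 0 with a flag.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    n = tp + fp + fn + tn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    undefined = (tp + fp) == 0
    prec = 0.0 if undefined else tp / (tp + fp)
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return ConfusionMetrics(tp, fp, fn, tn, (tp + tn) / n, sens, spec, prec, f1,
                            precision_undefined=undefined)


# ---------------------------------------------------------------------------
# Calibration + Brier
# ---------------------------------------------------------------------------

def calibration_and_brier(scores, labels, n_bins: int = 5
                          ) -> tuple[pd.DataFrame, float]:
    """Brier score plus a quantile-binned calibration curve.

    The curve rows are (mean predicted score, observed event rate, n) per
    quantile bin of the scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(scores) < n_bins:
        raise ValueError("need at least n_bins observations")
    brier = float(np.mean((scores - labels) ** 2))
    edges = np.unique(np.quantile(scores, np.linspace(0, 1, n_bins + 1)))
    bins = np.clip(np.searchsorted(edges[1:-1], scores, side="right"), 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = bins == b
        if sel.any():
            rows.append({"mean_score": scores[sel].mean(),
                         "event_rate": labels[sel].mean(),
                         "n": int(sel.sum())})
    return pd.DataFrame(rows), brier


# ---------------------------------------------------------------------------
# Decision curves
# ---------------------------------------------------------------------------

def decision_curve(scores, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit of treating at score >= p_t, across threshold probabilities.

    ``NB(p_t) = TP/n - (FP/n) * p_t/(1-p_t)``; the treat-all reference is
    ``prevalence - (1-prevalence) * p_t/(1-p_t)`` and treat-none is 0.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie in (0, 1)")
    n = len(labels)
    prevalence = labels.mean()
    rows = []
    for pt in thresholds:
        pred = scores >= pt
        tp = float((pred & (labels == 1)).sum())
        fp = float((pred & (labels == 0)).sum())
        odds = pt / (1 - pt)
        rows.append({"threshold": pt,
                     "net_benefit": tp / n - fp / n * odds,
                     "treat_all": prevalence - (1 - prevalence) * odds,
                     "treat_none": 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shapley attributions (Monte-Carlo permutation sampling)
# ---------------------------------------------------------------------------

@dataclass
class ShapReport:
    values: pd.DataFrame            # rows x features, signed attributions
    baseline: float                 # mean model score over the background
    mean_abs: pd.Series = field(init=False)
    mc_se: pd.Series | None = None  # per-row MC standard error of the sum
    efficiency_gap: pd.Series | None = None  # sum(phi) + baseline - score

    def __post_init__(self) -> None:
        self.mean_abs = self.values.abs().mean(axis=0).sort_values(ascending=False)


def shapley_attributions(score_fn, X: pd.DataFrame, background: pd.DataFrame,
                         n_permutations: int = 200, seed: int = 0) -> ShapReport:
    """Permutation-sampling Shapley values of ``score_fn`` over features.

    For each sampled permutation a background row is drawn; features are
    switched one by one from the background value to the explained row's
    value in permutation order, and each feature is credited with the
    resulting score change.  Deterministic given ``seed``; per-row sums
    telescope to score(x) - score(background draw), so the attributions
    satisfy efficiency up to Monte-Carlo error in the baseline.
    """
    import warnings as _warnings
    if n_permutations < 10:
        _warnings.warn("fewer than 10 permutations gives very noisy Shapley values")
    rng = np.random.default_rng(seed)
    cols = list(X.columns)
    d = len(cols)
    Xv = X.to_numpy(dtype=np.float64)
    Bv = background.to_numpy(dtype=np.float64)
    n = len(Xv)
    phi = np.zeros((n, d))
    totals = np.zeros((n_permutations, n))
    for t in range(n_permutations):
        perm = rng.permutation(d)
        b = Bv[rng.integers(len(Bv))]
        current = np.tile(b, (n, 1))
        prev = score_fn(pd.DataFrame(current, columns=cols, index=X.index))
        start = prev.copy()
        for j in perm:
            current[:, j] = Xv[:, j]
            cur = score_fn(pd.DataFrame(current, columns=cols, index=X.index))
            phi[:, j] += cur - prev
            prev = cur
        totals[t] = prev - start
    phi /= n_permutations
    baseline = float(np.mean(score_fn(background)))
    values = pd.DataFrame(phi, columns=cols, index=X.index)
    mc_se = pd.Series(totals.std(axis=0, ddof=1) / np.sqrt(n_permutations),
                      index=X.index)
    gap = pd.Series(phi.sum(axis=1) + baseline - np.asarray(score_fn(X)),
                    index=X.index)
    return ShapReport(values=values, baseline=baseline, mc_se=mc_se,
                      efficiency_gap=gap)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def evaluate_model(scores, labels, threshold: float = 0.5, n_bins: int = 5) -> dict:
    """One-stop evaluation: AUC+CI, confusion metrics, Brier, curves."""
    roc = roc_auc_delong(scores, labels)
    conf = confusion_metrics(scores, labels, threshold=threshold)
    curve, brier = calibration_and_brier(scores, labels, n_bins=n_bins)
    return {"roc": roc, "confusion": conf, "brier": brier,
            "calibration_curve": curve,
            "decision_curve": decision_curve(scores, labels)}
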