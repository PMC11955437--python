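"""Clinical statistics: per-SD logistic effects, risk cutoffs, survival.

The per-SD convention: binary covariates are z-scored before logistic
fitting, so reported odds ratios are per one-standard-deviation increment
of the indicator.  For a 2x2 table this has a closed form — the raw
log-odds ratio ln(ad/bc) times the covariate's population SD
sqrt(p(1-p)) — which equals the maximum-likelihood coefficient of a
univariate logistic fit on the z-scored indicator exactly.

Also provided: multivariable per-SD logistic regression (statsmodels MLE),
Youden-index cutoff selection on predicted scores, Kaplan-Meier medians
with two-group log-rank tests (lifelines), and the adjuvant-therapy
subgroup analysis stratified by predicted risk group.

``REFERENCE_TABLES`` holds the derivation-cohort 2x2 counts (n = 432, 186
LN-positive) of a published multicenter PDAC surgical cohort, used as a
fixed numerical reference for the closed-form procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats


@dataclass(frozen=True)
class TwoByTwo:
    """Counts: a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0 or self.total == 0:
            raise ValueError("counts must be non-negative with a positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def exposure_prevalence(self) -> float:
        return (self.a + self.b) / self.total


#: Derivation-cohort 2x2 counts (exposed cases, exposed controls,
#: unexposed cases, unexposed controls) for a 432-patient PDAC surgical
#: cohort; cases are LN-metastasis-positive patients.
REFERENCE_TABLES: dict[str, TwoByTwo] = {
    "sex_male": TwoByTwo(111, 134, 75, 112),
    "diabetes": TwoByTwo(57, 70, 129, 176),
    "hypertension": TwoByTwo(79, 108, 107, 138),
    "tbil_high": TwoByTwo(80, 71, 106, 175),
    "ca199_high": TwoByTwo(124, 129, 62, 117),
    "enlarged_ln": TwoByTwo(56, 41, 130, 205),
}


@dataclass
class LogisticRow:
    covariate: str
    coefficient: float        # per-SD log odds
    odds_ratio: float
    ci: tuple[float, float]
    p_value: float
    sd: float                 # covariate SD used for the per-SD scaling


def univariate_or_per_sd(table: TwoByTwo, name: str = "covariate") -> LogisticRow:
    """Closed-form per-SD univariate logistic result for a 2x2 table.

    Zero cells trigger the Haldane-Anscombe 0.5 continuity correction with
    a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        import warnings
        warnings.warn("zero cell: applying 0.5 continuity correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    p = table.exposure_prevalence
    sd = float(np.sqrt(p * (1 - p)))
    raw = float(np.log(a * d / (b * c)))
    coef = raw * sd
    se = sd * float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = coef / se
    ci = (float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se)))
    return LogisticRow(name, coef, float(np.exp(coef)), ci,
                       float(2 * stats.norm.sf(abs(z))), sd)


def reference_univariate_results() -> pd.DataFrame:
    """Per-SD univariate ORs for every reference 2x2 table."""
    rows = []
    for name, table in REFERENCE_TABLES.items():
        r = univariate_or_per_sd(table, name)
        rows.append({"covariate": name, "coefficient": r.coefficient,
                     "or": r.odds_ratio, "ci_low": r.ci[0], "ci_high": r.ci[1],
                     "p": r.p_value})
    return pd.DataFrame(rows).set_index("covariate")


def multivariate_logistic_per_sd(df: pd.DataFrame, covariates: list[str],
                                 label_col: str) -> pd.DataFrame:
    """Multivariable ML logistic regression on z-scored covariates.

    Returns a frame with per-SD coefficient, OR, Wald 95% CI and p per
    covariate.  Separation triggers a ridge-stabilised fallback (flagged
    in the ``stabilized`` column).
    """
    import statsmodels.api as sm
    X = df[covariates].to_numpy(dtype=np.float64)
    sds = X.std(axis=0)  # population convention, matching the closed form
    if (sds == 0).any():
        raise ValueError("constant covariate cannot be standardised")
    Z = (X - X.mean(axis=0)) / sds
    y = df[label_col].to_numpy(dtype=np.float64)
    design = sm.add_constant(Z)
    stabilized = False
    try:
        fit = sm.Logit(y, design).fit(disp=0)
        if not np.isfinite(fit.bse).all():
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, Exception):
        fit = sm.Logit(y, design).fit_regularized(alpha=1e-4, disp=0)
        stabilized = True
    coefs = np.asarray(fit.params)[1:]
    if hasattr(fit, "bse") and np.isfinite(np.asarray(fit.bse)).all():
        ses = np.asarray(fit.bse)[1:]
    else:
        ses = np.full(len(coefs), np.nan)
    rows = []
    for i, cov in enumerate(covariates):
        coef, se = coefs[i], ses[i]
        z = coef / se if se > 0 else np.nan
        rows.append({"covariate": cov, "coefficient": coef,
                     "or": np.exp(coef),
                     "ci_low": np.exp(coef - 1.96 * se),
                     "ci_high": np.exp(coef + 1.96 * se),
                     "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                     "stabilized": stabilized})
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# Risk stratification
# ---------------------------------------------------------------------------

@dataclass
class RiskStratification:
    cutoff: float
    groups: np.ndarray   # "high" where score >= cutoff else "low"
    youden: float        # sensitivity + specificity - 1 at the cutoff


def youden_cutoff(scores, labels) -> RiskStratification:
    """Cutoff maximising Youden's J over the observed score values.

    The high-risk rule is ``score >= cutoff``; ties in J go to the lower
    cutoff.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes present")
    candidates = np.unique(scores)
    n_pos, n_neg = (labels == 1).sum(), (labels == 0).sum()
    best = None
    for cut in candidates:  # ascending, so first max wins -> lower cutoff on ties
        pred = scores >= cut
        j = (pred & (labels == 1)).sum() / n_pos - (pred & (labels == 0)).sum() / n_neg
        if best is None or j > best[0] + 1e-12:
            best = (j, cut)
    j, cut = best
    return RiskStratification(cutoff=float(cut),
                              groups=np.where(scores >= cut, "high", "low"),
                              youden=float(j))


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    medians: dict              # group -> median survival (np.inf = not reached)
    chi_square: float | None
    p_value: float | None
    group_sizes: dict


def km_median(times, events) -> float:
    """Median survival: earliest time with S(t) <= 0.5 (inf if not reached)."""
    kmf = KaplanMeierFitter().fit(np.asarray(times), np.asarray(events))
    return float(kmf.median_survival_time_)


def km_logrank(times, events, groups, medians: bool = True) -> KMResult:
    """Per-group KM medians plus the two-group log-rank test.

    With a single group only the median is returned; more than two groups
    are rejected (the pipeline contrasts are all two-group).  Pass
    ``medians=False`` to skip the product-limit fits (e.g. in large null
    simulations where only the p-value matters).
    """
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    if events.sum() < 1:
        raise ValueError("need at least one event")
    uniq = [g for g in pd.unique(groups)]
    if any((groups == g).sum() == 0 for g in uniq) or len(uniq) == 0:
        raise ValueError("every group must be non-empty")
    medians = {g: km_median(times[groups == g], events[groups == g])
               for g in uniq} if medians else {}
    sizes = {g: int((groups == g).sum()) for g in uniq}
    if len(uniq) == 1:
        return KMResult(medians, None, None, sizes)
    if len(uniq) != 2:
        raise ValueError("log-rank contrast expects exactly 2 groups")
    g0, g1 = uniq
    res = logrank_test(times[groups == g0], times[groups == g1],
                       events[groups == g0], events[groups == g1])
    return KMResult(medians, float(res.test_statistic), float(res.p_value), sizes)


def adjuvant_subgroup_analysis(df: pd.DataFrame, risk_col: str = "risk_group",
                               treat_col: str = "adjuvant",
                               time_col: str = "os_days",
                               event_col: str = "os_event") -> dict[str, KMResult]:
    """Treated-vs-untreated KM/log-rank within each predicted risk group.

    Strata with a missing treatment arm are skipped with a warning.
    """
    import warnings
    out: dict[str, KMResult] = {}
    for risk in pd.unique(df[risk_col]):
        sub = df[df[risk_col] == risk]
        arms = pd.unique(sub[treat_col])
        if len(arms) < 2:
            warnings.warn(f"risk group {risk!r} lacks both treatment arms; skipped")
            continue
        out[str(risk)] = km_logrank(sub[time_col], sub[event_col],
                                    np.where(sub[treat_col] == 1, "treated", "untreated"))
    return out
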