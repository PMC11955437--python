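"""End-to-end desk-scale study: synthetic cohort -> habitats -> models -> stats.

``run_end_to_end`` executes the whole analysis on synthetic data with a
known ground truth: it generates a derivation and a validation cohort of
multiphase studies whose enhancement kinetics, habitat composition and
clinical covariates all carry label-dependent signal, computes enhancement
maps, fits the population habitat model on pooled derivation voxels,
extracts whole-tumor and per-habitat features, runs the selection cascade
per information source, fits the model zoo (per-sequence radiomics and
habitat models, combined habitat models, clinical model, RH and RHC
stacks), evaluates every model on the held-out validation cohort, and
finishes with Youden-cutoff risk stratification and Kaplan-Meier /
log-rank survival contrasts.

Validation patients never touch any fitting step: the habitat model,
standardisation, selection and all classifiers are frozen on the
derivation cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import modeling, survival
from .evaluation import roc_auc_delong
from .habitat import HabitatClusterer, assign_habitats, build_voxel_space
from .imaging import compute_enhancement_maps
from .modeling import _svm_meta
from .selection import CascadeSelector
from .synth import (SynthClinicalSpec, SynthVolumeSpec, VoxelMixtureSpec,
                    generate_clinical_cohort, generate_multiphase_study)
from .texture import FeatureSpec, extract_features

T1_SEQUENCES = ("T1_Pre", "T1_A", "T1_V", "T1_D")
MAP_SEQUENCES = ("Enhanced_A", "Enhanced_V", "Enhanced_D")
ALL_SEQUENCES = T1_SEQUENCES + MAP_SEQUENCES


@dataclass
class RunConfig:
    """Configuration of the desk-scale synthetic study.

    Cohort sizes follow the source-study 432/109 split scaled down, with
    the validation cohort enlarged so held-out AUC contrasts have adequate
    power at desk scale.  The imaging generator plants three habitat
    kinetics whose mixing weights and hyper-enhancing component shift with
    the LN label, so radiomics, habitat and clinical sources each carry
    partial, complementary signal.
    """

    n_derivation: int = 140
    n_validation: int = 400
    grid_shape: tuple = (18, 18, 18)
    tumor_radius: float = 4.5
    phase_baseline: float = 100.0
    noise_sd: float = 2.0
    mixture_sigma: float = 0.08
    weights_neg: tuple = (0.22, 0.48, 0.30)
    weights_pos: tuple = (0.20, 0.47, 0.33)
    #: additive shift of the hyper-enhancing component's mean for LN+ tumors
    #: (the habitat-specific signal)
    pos_mean_shift: float = 0.12
    #: sd of the per-patient, per-component random kinetic offsets
    patient_mean_sd: float = 0.15
    #: Dirichlet concentration of the per-patient habitat-weight jitter
    weight_concentration: float = 40.0
    #: LN+ tumors run more elongated (the morphology-specific signal seen by
    #: whole-tumor shape features): multiplicative factor on the leading
    #: semi-axis ratio, plus a per-patient log-normal elongation jitter
    pos_elongation_factor: float = 1.13
    elongation_log_sd: float = 0.12
    #: label-independent per-patient size jitter
    radius_log_sd: float = 0.08
    clinical_per_sd_log_odds: tuple = (0.5, 0.5, 0.55)
    k_candidates: tuple = (2, 3, 4)
    kmeans_n_init: int = 4
    voxel_subsample_cap: int = 20_000
    #: (filter, feature class) extraction cells of the desk-scale menu
    feature_menu: tuple = (("original", "firstorder"),
                           ("binomialblur1", "ngtdm"))
    n_bins: int = 16
    k1: int = 40
    k2: int = 15
    lasso_cv: int = 3
    lasso_n_penalties: int = 20
    #: min-deviance penalty choice: at desk-scale n the 1-SE rule is too
    #: aggressive and occasionally empties a pool's selection
    lasso_one_se: bool = False
    stack_folds: int = 5
    seed: int = 0


def _mixture_for(cfg: RunConfig, label: int, seed: int) -> VoxelMixtureSpec:
    """Patient-specific kinetics: label effects on top of biological noise.

    Every patient gets a random kinetic offset (shared across components)
    and Dirichlet-jittered habitat weights, so the planted label effects —
    a hyper-enhancing-component mean shift and a habitat-weight shift —
    are partially masked by between-patient variability, keeping model
    AUCs in a realistic range instead of trivially separable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    base = np.array(((0.2, 0.3, 0.35), (0.7, 0.9, 0.8), (1.3, 1.6, 1.4)))
    means = base + rng.normal(0.0, cfg.patient_mean_sd, size=(3, 3))
    if label == 1:
        means[2] += cfg.pos_mean_shift
    w = np.asarray(cfg.weights_pos if label == 1 else cfg.weights_neg)
    w = rng.dirichlet(cfg.weight_concentration * w)
    w = w / w.sum()
    return VoxelMixtureSpec(n_components=3, weights=tuple(w),
                            means=tuple(map(tuple, means)), sigma=cfg.mixture_sigma,
                            n_voxels=1, seed=seed)


def _generate_cohort(cfg: RunConfig, labels: np.ndarray, seeds: np.ndarray):
    """Per-patient PhaseSets and enhancement maps, keyed by patient index."""
    maps = {}
    phases = {}
    half_extent = min(s for s in cfg.grid_shape) / 2.0
    for pid, (label, seed) in enumerate(zip(labels, seeds)):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
        radius = cfg.tumor_radius * float(np.exp(rng.normal(0, cfg.radius_log_sd)))
        elong = float(np.exp(rng.normal(0, cfg.elongation_log_sd)))
        if label == 1:
            elong *= cfg.pos_elongation_factor
        elong = float(np.clip(elong, 0.75, 1.6))
        # volume-preserving ellipsoid: one long axis, two equal short axes
        ratios = (elong, 1.0 / np.sqrt(elong), 1.0 / np.sqrt(elong))
        radius = min(radius, 0.95 * half_extent / max(ratios))
        spec = SynthVolumeSpec(grid_shape=cfg.grid_shape,
                               tumor_radius=radius,
                               axis_ratios=ratios,
                               phase_baseline=cfg.phase_baseline,
                               noise_sd=cfg.noise_sd,
                               mixture=_mixture_for(cfg, int(label), int(seed)),
                               seed=int(seed))
        ps, _ = generate_multiphase_study(spec)
        phases[pid] = ps
        maps[pid] = compute_enhancement_maps(ps, mode="ratio")
    return phases, maps


def _patient_features(cfg: RunConfig, phases, maps, labeling) -> pd.DataFrame:
    specs = [FeatureSpec(filter=f, feature_class=c, n_bins=cfg.n_bins)
             for f, c in cfg.feature_menu]
    rows = {}
    for pid, ps in phases.items():
        volumes = {"T1_Pre": ps.pre.data, "T1_A": ps.arterial.data,
                   "T1_V": ps.venous.data, "T1_D": ps.delayed.data}
        em = maps[pid]
        volumes.update({name: vol.data for name, vol in em.as_dict().items()})
        tumor = ps.mask_bool
        habs = labeling.label_volumes[pid]
        regions = {"tumor": tumor}
        for h in range(1, int(habs.max()) + 1):
            regions[f"habitat{h}"] = (habs == h) & tumor
        rows[pid] = extract_features(volumes, regions, specs,
                                     voxel_size=ps.pre.voxel_size)
    return pd.DataFrame.from_dict(rows, orient="index")


def _feature_pools(columns: pd.Index) -> dict[str, list[str]]:
    """Partition feature names into the per-model pools of the zoo."""
    pools: dict[str, list[str]] = {}
    cols = list(columns)
    tumor_shape = [c for c in cols if c.startswith("tumor_shape_")]
    for seq in ALL_SEQUENCES:
        # whole-tumor radiomics includes the (sequence-independent) shape
        # block; habitat models are subregion intensity/texture only.
        pools[f"Radiomic_{seq}"] = [c for c in cols
                                    if c.startswith(f"{seq}_tumor_")] + tumor_shape
        pools[f"Habitat_{seq}"] = [c for c in cols
                                   if c.startswith(f"{seq}_habitat")]
    pools["Original_habitat"] = sum((pools[f"Habitat_{s}"] for s in T1_SEQUENCES), [])
    pools["Enhanced_habitat"] = sum((pools[f"Habitat_{s}"] for s in MAP_SEQUENCES), [])
    pools["Habitat"] = pools["Original_habitat"] + pools["Enhanced_habitat"]
    pools["RadiomicsAll"] = sorted(
        {c for s in ALL_SEQUENCES for c in pools[f"Radiomic_{s}"]})
    return pools


def _cascade_model(cfg: RunConfig, X: pd.DataFrame, y: np.ndarray, pool: list[str],
                   seed: int) -> modeling.LogisticScorer:
    """Selection cascade on a feature pool followed by a logistic base model."""
    sub = X[pool]
    # drop all-missing / constant columns before the screen
    usable = [c for c in pool
              if sub[c].notna().any() and np.nanstd(sub[c].to_numpy(float)) > 0]
    filled = sub[usable].fillna(sub[usable].median())
    cascade = CascadeSelector(k1=cfg.k1, k2=cfg.k2, cv=cfg.lasso_cv,
                              one_se=cfg.lasso_one_se,
                              random_state=seed).fit(filled, y)
    model = modeling.LogisticScorer(features=cascade.selected_features_).fit(X, y)
    model.cascade_ = cascade
    return model


class _CascadeBase(modeling.LogisticScorer):
    """Cloneable base model: refits its own cascade on whatever fold it sees."""

    def __init__(self, pool: list[str] | None = None, cfg: RunConfig | None = None,
                 seed: int = 0, features=None, C: float = 100.0,
                 impute_median: bool = True):
        super().__init__(features=features, C=C, impute_median=impute_median)
        self.pool = pool
        self.cfg = cfg
        self.seed = seed

    def fit(self, X, y):
        fitted = _cascade_model(self.cfg, X, np.asarray(y), self.pool, self.seed)
        self.features = fitted.features
        self.cascade_ = fitted.cascade_
        return super().fit(X, y)


@dataclass
class RunResult:
    """Artifacts of one end-to-end run."""

    habitat_model: HabitatClusterer
    cohort_proportions: pd.Series
    derivation: pd.DataFrame
    validation: pd.DataFrame
    val_scores: pd.DataFrame            # validation patients x model scores
    aucs: pd.Series                     # held-out validation AUC per model
    oof_aucs: pd.Series                 # derivation out-of-fold AUC per model
    cutoff: float
    risk_groups: np.ndarray
    survival_results: dict
    selected_features: dict = field(default_factory=dict)


def run_end_to_end(cfg: RunConfig | None = None) -> RunResult:
    cfg = cfg or RunConfig()
    master = np.random.SeedSequence(cfg.seed)
    seeds = master.generate_state(6) % (2 ** 31)

    n_total = cfg.n_derivation + cfg.n_validation
    clin_spec = SynthClinicalSpec(n_patients=n_total,
                                  per_sd_log_odds=cfg.clinical_per_sd_log_odds,
                                  seed=int(seeds[0]))
    cohort = generate_clinical_cohort(clin_spec)
    labels = cohort["ln_metastasis"].to_numpy()
    patient_seeds = np.random.SeedSequence(int(seeds[1])).generate_state(n_total) % (2 ** 31)

    phases, maps = _generate_cohort(cfg, labels, patient_seeds)
    der_ids = list(range(cfg.n_derivation))
    val_ids = list(range(cfg.n_derivation, n_total))

    # --- habitats: fitted on pooled derivation voxels only -----------------
    space = build_voxel_space({pid: maps[pid] for pid in der_ids},
                              subsample_cap=cfg.voxel_subsample_cap,
                              seed=int(seeds[2]))
    hab = HabitatClusterer(k_candidates=cfg.k_candidates, n_init=cfg.kmeans_n_init,
                           random_state=int(seeds[3]) % (2 ** 31)).fit(space.X)
    labeling = assign_habitats(hab, maps, space.transform)

    features = _patient_features(cfg, phases, maps, labeling)
    features = pd.concat([features, cohort[list(modeling.CLINICAL_COVARIATES)]], axis=1)
    X_der, X_val = features.loc[der_ids], features.loc[val_ids]
    y_der, y_val = labels[der_ids], labels[val_ids]

    pools = _feature_pools(features.columns)
    base_seed = int(seeds[4]) % (2 ** 31)

    # --- base models: per-sequence radiomics (for the Radiomics LR stack)
    # and the two pooled sources backing the RH/RHC stacks -------------------
    base_names = [f"Radiomic_{s}" for s in ALL_SEQUENCES] + \
        ["RadiomicsAll", "Habitat", "Original_habitat", "Enhanced_habitat"]
    base_models = {name: _CascadeBase(pool=pools[name], cfg=cfg, seed=base_seed)
                   for name in base_names}
    base_models["Clinical"] = modeling.LogisticScorer(
        features=list(modeling.CLINICAL_COVARIATES), C=1e6)
    oof, _ = modeling.out_of_fold_scores(base_models, X_der, y_der,
                                         n_splits=cfg.stack_folds, seed=base_seed)
    from sklearn.base import clone
    fitted_bases = {name: clone(m).fit(X_der, y_der)
                    for name, m in base_models.items()}
    val_base = pd.DataFrame({name: m.score_samples(X_val)
                             for name, m in fitted_bases.items()}, index=X_val.index)

    val_scores = pd.DataFrame(index=X_val.index)
    oof_scores = pd.DataFrame(index=X_der.index)
    selected = {name: m.features for name, m in fitted_bases.items()
                if isinstance(m, _CascadeBase)}

    def _meta(columns: list[str], extra: list[str] | None, kind: str, name: str):
        tr = oof[columns].to_numpy(float)
        va = val_base[columns].to_numpy(float)
        if extra:
            tr = np.hstack([tr, X_der[extra].to_numpy(float)])
            va = np.hstack([va, X_val[extra].to_numpy(float)])
        if kind == "lr":
            learner = Pipeline([("scale", StandardScaler()),
                                ("logit", LogisticRegression(C=100.0, max_iter=2000))])
        else:
            learner = Pipeline([("scale", StandardScaler()),
                                ("svm", _svm_meta(base_seed))])
        learner.fit(tr, y_der)
        val_scores[name] = learner.predict_proba(va)[:, 1]
        oof_scores[name] = learner.predict_proba(tr)[:, 1]

    radiomic_cols = [f"Radiomic_{s}" for s in ALL_SEQUENCES]
    rh_cols = radiomic_cols + ["RadiomicsAll", "Habitat"]
    _meta(radiomic_cols, None, "lr", "Radiomics")
    _meta(rh_cols, None, "lr", "RH")
    _meta(rh_cols, list(modeling.CLINICAL_COVARIATES), "svm", "RHC")

    for name in ("Habitat", "Original_habitat", "Enhanced_habitat", "Clinical"):
        val_scores[name] = val_base[name]
        oof_scores[name] = oof[name]

    aucs = pd.Series({name: roc_auc_delong(val_scores[name], y_val).auc
                      for name in val_scores.columns})
    oof_aucs = pd.Series({name: roc_auc_delong(oof_scores[name], y_der).auc
                          for name in oof_scores.columns})

    # --- risk stratification + survival on the validation cohort -----------
    strat = survival.youden_cutoff(val_scores["RHC"], y_val)
    val_clin = cohort.loc[val_ids].copy()
    val_clin["risk_group"] = strat.groups
    surv = {
        "rfs": survival.km_logrank(val_clin["rfs_days"], val_clin["rfs_event"],
                                   strat.groups),
        "os": survival.km_logrank(val_clin["os_days"], val_clin["os_event"],
                                  strat.groups),
        "adjuvant": survival.adjuvant_subgroup_analysis(val_clin),
    }

    return RunResult(habitat_model=hab,
                     cohort_proportions=labeling.cohort_proportions,
                     derivation=X_der.assign(ln_metastasis=y_der),
                     validation=X_val.assign(ln_metastasis=y_val),
                     val_scores=val_scores, aucs=aucs, oof_aucs=oof_aucs,
                     cutoff=strat.cutoff, risk_groups=strat.groups,
                     survival_results=surv, selected_features=selected)
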