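"""Synthetic-data generators for the habitat-imaging pipeline.

Three generators cover every input the pipeline needs:

* a voxel feature space drawn from a k-component Gaussian mixture over
  (arterial, venous, delayed) enhancement-ratio vectors, with controllable
  component weights and separation — the stand-in for pooled tumor voxels;
* multiphase 3-D volumes in which tumor voxels follow the planted
  enhancement kinetics of their habitat plus additive Gaussian noise, so
  enhancement maps, clustering and texture extraction can be exercised on
  image data with a known ground truth;
* a clinical cohort with binary covariates at stated prevalences, a
  lymph-node-metastasis label from a logistic model with stated per-SD
  log-odds, and exponential recurrence-free/overall survival times with
  group-specific medians and independent random censoring.

Default mixture weights (0.163, 0.464, 0.373) mirror the habitat
proportions of the study regime the pipeline models, so recovery tests run
under realistic class imbalance.  All randomness flows from one integer
seed per spec; sub-streams are derived with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import PhaseSet, VolumeGrid

DEFAULT_WEIGHTS = (0.163, 0.464, 0.373)
#: well-separated default component means in (arterial, venous, delayed)
#: enhancement-ratio units: hypo-, iso- and hyper-enhancing kinetics.
DEFAULT_MEANS = ((0.2, 0.3, 0.35), (0.7, 0.9, 0.8), (1.3, 1.6, 1.4))


class ParameterError(ValueError):
    """Raised when a generator spec violates its invariants."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# Voxel mixture
# ---------------------------------------------------------------------------

@dataclass
class VoxelMixtureSpec:
    """A k-component Gaussian mixture over 3-vector enhancement ratios."""

    n_components: int = 3
    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    means: tuple[tuple[float, float, float], ...] = DEFAULT_MEANS
    covariances: tuple | None = None   # per-component 3x3 SPD; default sigma^2 I
    sigma: float = 0.05                # isotropic sd used when covariances is None
    n_voxels: int = 30_000
    seed: int = 0

    def resolved_covariances(self) -> np.ndarray:
        if self.covariances is None:
            return np.stack([self.sigma ** 2 * np.eye(3)] * self.n_components)
        return np.asarray(self.covariances, dtype=np.float64)

    def validate(self) -> None:
        if self.n_components < 1:
            raise ParameterError("n_components must be >= 1")
        w = np.asarray(self.weights, dtype=np.float64)
        if len(w) != self.n_components:
            raise ParameterError("weights length must equal n_components")
        if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ParameterError("weights must be non-negative and sum to 1")
        means = np.asarray(self.means, dtype=np.float64)
        if means.shape != (self.n_components, 3):
            raise ParameterError("means must be n_components x 3")
        covs = self.resolved_covariances()
        if covs.shape != (self.n_components, 3, 3):
            raise ParameterError("covariances must be n_components x 3 x 3")
        for i, c in enumerate(covs):
            if not np.allclose(c, c.T):
                raise ParameterError(f"covariance {i} is not symmetric")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ParameterError(f"covariance {i} is not positive-definite")
        if self.n_voxels < 1:
            raise ParameterError("n_voxels must be >= 1")


def generate_voxel_space(spec: VoxelMixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_voxels`` i.i.d. rows from the mixture.

    Returns ``(X, labels)`` with X of shape (n_voxels, 3) and integer
    component labels in 0..k-1 for recovery tests.  Deterministic per seed.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    labels = rng.choice(spec.n_components, size=spec.n_voxels, p=np.asarray(spec.weights))
    means = np.asarray(spec.means, dtype=np.float64)
    covs = spec.resolved_covariances()
    X = np.empty((spec.n_voxels, 3))
    for comp in range(spec.n_components):
        idx = np.flatnonzero(labels == comp)
        if idx.size:
            X[idx] = rng.multivariate_normal(means[comp], covs[comp], size=idx.size,
                                             method="cholesky")
    return X, labels


# ---------------------------------------------------------------------------
# Multiphase volumes with planted habitats
# ---------------------------------------------------------------------------

@dataclass
class SynthVolumeSpec:
    """One synthetic multiphase study: a spherical tumor with planted habitats."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius: float = 9.0          # mm (effective radius; see axis_ratios)
    #: per-axis semi-axis scale factors of the tumor ellipsoid (1,1,1 =
    #: sphere); the semi-axis along axis i is tumor_radius * axis_ratios[i]
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    habitat_geometry: str = "concentric-shells"   # or "random-blobs"
    phase_baseline: float = 100.0      # pre-contrast signal units
    noise_sd: float = 2.0              # additive signal noise
    mixture: VoxelMixtureSpec = field(default_factory=VoxelMixtureSpec)
    seed: int = 0

    def validate(self) -> None:
        self.mixture.validate()
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.habitat_geometry not in ("concentric-shells", "random-blobs"):
            raise ParameterError(f"unknown habitat_geometry {self.habitat_geometry!r}")
        if min(self.axis_ratios) <= 0:
            raise ParameterError("axis_ratios must be positive")
        half_extent = min(s * v for s, v in zip(self.grid_shape, self.voxel_size)) / 2.0
        if self.tumor_radius * max(self.axis_ratios) >= half_extent:
            raise ParameterError(
                f"tumor (radius {self.tumor_radius}, axis ratios {self.axis_ratios}) "
                f"does not fit inside the grid (half-extent {half_extent})")


def _effective_radius(spec: SynthVolumeSpec) -> np.ndarray:
    """Per-voxel ellipsoidal radius (mm): the tumor is r <= tumor_radius."""
    centers = [(s - 1) / 2.0 for s in spec.grid_shape]
    coords = np.indices(spec.grid_shape).reshape(3, -1).T.astype(np.float64)
    scaled = (coords - centers) * np.asarray(spec.voxel_size) / np.asarray(spec.axis_ratios)
    return np.linalg.norm(scaled, axis=1)


def _habitat_labels(spec: SynthVolumeSpec, mask: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Assign habitat ids 1..k to masked voxels per the requested geometry."""
    k = spec.mixture.n_components
    weights = np.asarray(spec.mixture.weights)
    centers = [(s - 1) / 2.0 for s in spec.grid_shape]
    coords = np.indices(spec.grid_shape).reshape(3, -1).T.astype(np.float64)
    r = _effective_radius(spec)
    labels = np.zeros(mask.size, dtype=np.int32)
    inside = mask.reshape(-1)
    if spec.habitat_geometry == "concentric-shells":
        # shell radii chosen so shell volume fractions equal the weights
        # (r^3 proportional to cumulative volume); habitat 1 is the core.
        cum = np.concatenate([[0.0], np.cumsum(weights)])
        edges = spec.tumor_radius * np.cbrt(cum)
        shell = np.clip(np.searchsorted(edges[1:-1], r[inside], side="right"), 0, k - 1)
        labels[inside] = shell + 1
    else:
        n_seeds = max(4 * k, 16)
        seed_pos = rng.uniform(-spec.tumor_radius, spec.tumor_radius, size=(n_seeds, 3))
        seed_hab = rng.choice(k, size=n_seeds, p=weights) + 1
        d = np.linalg.norm(
            ((coords[inside] - centers) * np.asarray(spec.voxel_size))[:, None, :]
            - seed_pos[None, :, :], axis=2)
        labels[inside] = seed_hab[np.argmin(d, axis=1)]
    return labels.reshape(spec.grid_shape)


def generate_multiphase_study(spec: SynthVolumeSpec) -> tuple[PhaseSet, np.ndarray]:
    """Build a PhaseSet and the true habitat label volume.

    Tumor voxels of habitat h carry phase signals
    ``phase_baseline * (1 + r_phase)`` with the 3-vector r drawn from mixture
    component h, plus N(0, noise_sd) noise on every voxel of every phase.
    Background voxels have no planted enhancement.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    rng_geom, rng_ratio, rng_noise = (np.random.default_rng(s) for s in ss)

    r = _effective_radius(spec)
    mask = (r <= spec.tumor_radius).reshape(spec.grid_shape)
    habitats = _habitat_labels(spec, mask, rng_geom)

    means = np.asarray(spec.mixture.means)
    covs = spec.mixture.resolved_covariances()
    ratios = np.zeros(spec.grid_shape + (3,))
    for h in range(1, spec.mixture.n_components + 1):
        idx = habitats == h
        n = int(idx.sum())
        if n:
            ratios[idx] = rng_ratio.multivariate_normal(
                means[h - 1], covs[h - 1], size=n, method="cholesky")

    affine = np.diag(list(spec.voxel_size) + [1.0])
    base = spec.phase_baseline

    def _phase(ratio_channel: np.ndarray | None) -> VolumeGrid:
        signal = np.full(spec.grid_shape, base)
        if ratio_channel is not None:
            signal = signal + base * ratio_channel * mask
        if spec.noise_sd > 0:
            signal = signal + rng_noise.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        return VolumeGrid(signal, affine)

    ps = PhaseSet(
        pre=_phase(None),
        arterial=_phase(ratios[..., 0]),
        venous=_phase(ratios[..., 1]),
        delayed=_phase(ratios[..., 2]),
        mask=VolumeGrid(mask.astype(np.float64), affine),
    )
    return ps, habitats


# ---------------------------------------------------------------------------
# Clinical cohort + survival
# ---------------------------------------------------------------------------

@dataclass
class SynthClinicalSpec:
    """A synthetic surgical cohort with planted covariate effects.

    ``per_sd_log_odds`` are the log-odds of LN metastasis per one-SD
    increment of each (z-scored) binary covariate; defaults follow the
    multivariable effect sizes of the modelled study regime (CA19-9, TBil,
    radiologically enlarged LN).  Survival times are exponential with
    group-specific medians, the simplest model consistent with
    median-based reporting; censoring is independent-exponential with
    expected censored fraction ``censoring_rate``.
    """

    n_patients: int = 432
    covariate_names: tuple[str, ...] = ("ca199_high", "tbil_high", "enlarged_ln")
    covariate_prevalences: tuple[float, ...] = (0.586, 0.350, 0.225)
    per_sd_log_odds: tuple[float, ...] = (0.221, 0.217, 0.278)
    baseline_ln_rate: float = 0.431
    treated_rate: float = 0.5
    #: median survival (days) per endpoint, risk group and treatment arm
    rfs_median_by_group: dict = field(default_factory=lambda: {
        ("low", "treated"): 600.0, ("low", "untreated"): 600.0,
        ("high", "treated"): 400.0, ("high", "untreated"): 331.0})
    os_median_by_group: dict = field(default_factory=lambda: {
        ("low", "treated"): 1400.0, ("low", "untreated"): 1200.0,
        ("high", "treated"): 908.0, ("high", "untreated"): 465.0})
    censoring_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if len(self.covariate_prevalences) != len(self.covariate_names) or \
                len(self.per_sd_log_odds) != len(self.covariate_names):
            raise ParameterError("covariate fields must have matching lengths")
        for p in self.covariate_prevalences:
            _check_prob("covariate prevalence", p)
        _check_prob("baseline_ln_rate", self.baseline_ln_rate)
        _check_prob("treated_rate", self.treated_rate)
        _check_prob("censoring_rate", self.censoring_rate)
        for table in (self.rfs_median_by_group, self.os_median_by_group):
            for key, med in table.items():
                if med <= 0:
                    raise ParameterError(f"median for group {key} must be > 0")


def generate_clinical_cohort(spec: SynthClinicalSpec) -> pd.DataFrame:
    """Sample a cohort table: covariates, LN label, therapy flag, RFS/OS.

    Columns: one 0/1 column per covariate, ``ln_metastasis``, ``adjuvant``,
    ``rfs_days``/``rfs_event``, ``os_days``/``os_event``.  The latent risk
    group used for survival medians is the true LN label (high risk = LN+).
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed).spawn(4)
    rng_cov, rng_label, rng_surv, rng_cens = (np.random.default_rng(s) for s in ss)
    n = spec.n_patients
    prev = np.asarray(spec.covariate_prevalences)
    X = (rng_cov.random((n, len(prev))) < prev).astype(np.int64)

    sd = np.sqrt(prev * (1 - prev))
    z = (X - prev) / sd
    intercept = np.log(spec.baseline_ln_rate / (1 - spec.baseline_ln_rate))
    eta = intercept + z @ np.asarray(spec.per_sd_log_odds)
    label = (rng_label.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int64)
    treated = (rng_label.random(n) < spec.treated_rate).astype(np.int64)

    risk = np.where(label == 1, "high", "low")
    arm = np.where(treated == 1, "treated", "untreated")

    def _endpoint(table: dict) -> tuple[np.ndarray, np.ndarray]:
        medians = np.array([table[(r, a)] for r, a in zip(risk, arm)])
        scale = medians / np.log(2.0)
        times = rng_surv.exponential(scale)
        events = np.ones(n, dtype=np.int64)
        q = spec.censoring_rate
        if q > 0:
            # independent exponential censoring whose rate is q/(1-q) times
            # the event rate: expected censored fraction is exactly q and
            # the Kaplan-Meier estimator stays consistent.
            cens_times = rng_cens.exponential(scale * (1 - q) / q)
            censored = cens_times < times
            times = np.minimum(times, cens_times)
            events[censored] = 0
        return times, events

    rfs_t, rfs_e = _endpoint(spec.rfs_median_by_group)
    os_t, os_e = _endpoint(spec.os_median_by_group)

    df = pd.DataFrame(X, columns=list(spec.covariate_names))
    df["ln_metastasis"] = label
    df["adjuvant"] = treated
    df["rfs_days"], df["rfs_event"] = rfs_t, rfs_e
    df["os_days"], df["os_event"] = os_t, os_e
    df.index.name = "patient_id"
    return df


def write_clinical_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path)


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")
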