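"""Voxel habitat clustering: feature space, Calinski–Harabasz, K-means.

Tumor voxels are described by their (arterial, venous, delayed)
enhancement-ratio 3-vector, z-scored over the pooled derivation cohort.
:class:`HabitatClusterer` fits K-means for a range of candidate cluster
counts, scores each with the Calinski–Harabasz criterion, keeps the best k,
and relabels clusters canonically by ascending mean arterial enhancement so
habitat ids are stable across runs (habitat 1 = least arterially enhancing).
The fitted model is applied to every cohort, giving population-level
habitats with per-patient subregion label volumes and proportion summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .imaging import EnhancementMaps, InputError, ZScoreTransform, zscore_within_mask


@dataclass
class VoxelFeatureSpace:
    """Pooled masked-voxel matrix (n_voxels x 3, z-scored) with provenance."""

    X: np.ndarray
    patient_ids: np.ndarray       # one entry per row
    voxel_index: np.ndarray       # linear voxel coordinate per row
    transform: ZScoreTransform

    def __post_init__(self) -> None:
        if not np.isfinite(self.X).all():
            raise InputError("voxel feature space contains non-finite values")


def _masked_vectors(maps: EnhancementMaps) -> tuple[np.ndarray, np.ndarray]:
    mask = maps.mask.data > 0.5
    stacked = np.stack([maps.enhanced_a.data[mask], maps.enhanced_v.data[mask],
                        maps.enhanced_d.data[mask]], axis=1)
    return stacked, np.flatnonzero(mask.reshape(-1))


def build_voxel_space(maps_by_patient: dict[object, EnhancementMaps],
                      subsample_cap: int | None = 200_000,
                      seed: int = 0) -> VoxelFeatureSpace:
    """Pool masked voxel 3-vectors across patients and z-score the pool.

    The z-scoring transform is fitted on this pool and stored for reuse on
    held-out patients.  If the pool exceeds ``subsample_cap`` rows a seeded
    uniform subsample of exactly that size is taken.
    """
    rows, pids, vidx = [], [], []
    for pid, maps in maps_by_patient.items():
        vecs, lin = _masked_vectors(maps)
        if not np.isfinite(vecs).all():
            raise InputError(f"non-finite enhancement values inside mask for patient {pid!r}")
        rows.append(vecs)
        pids.extend([pid] * len(vecs))
        vidx.append(lin)
    X = np.concatenate(rows, axis=0)
    pids = np.asarray(pids, dtype=object)
    vidx = np.concatenate(vidx)
    if subsample_cap is not None and len(X) > subsample_cap:
        keep = np.random.default_rng(seed).choice(len(X), size=subsample_cap, replace=False)
        keep.sort()
        X, pids, vidx = X[keep], pids[keep], vidx[keep]
    Xz, transform = zscore_within_mask(X)
    return VoxelFeatureSpace(Xz, pids, vidx, transform)


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski–Harabasz variance-ratio criterion.

    ``[B/(k-1)] / [W/(n-k)]`` with B and W the between- and within-cluster
    sums of squared distances to the respective centroids.  Degenerate
    zero-within-dispersion clusterings return +inf.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = len(X), len(uniq)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    overall = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for lab in uniq:
        pts = X[labels == lab]
        if len(pts) == 0:
            raise ValueError(f"cluster {lab!r} is empty")
        c = pts.mean(axis=0)
        between += len(pts) * float(((c - overall) ** 2).sum())
        within += float(((pts - c) ** 2).sum())
    if within == 0.0:
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


class HabitatClusterer(BaseEstimator, ClusterMixin):
    """K-means habitat model with Calinski–Harabasz selection of k.

    Parameters
    ----------
    k_candidates : iterable of int, default 2..9
        Candidate cluster counts; for each, K-means (k-means++ init,
        ``n_init`` restarts, best inertia kept) is fitted and scored.
    n_init : int
        K-means restarts per candidate.
    random_state : int
        Seed controlling all restarts; fits are deterministic given it.

    Attributes
    ----------
    k_ : selected number of habitats (argmax CH, ties to smaller k).
    cluster_centers_ : (k_, 3) centroids in z-scored units, canonically
        ordered by ascending mean arterial enhancement (column 0).
    ch_scores_ : dict mapping each candidate k to its CH value.
    labels_ : canonical labels (0-based) of the training voxels.
    inertia_ : within-cluster sum of squares of the selected model.
    """

    def __init__(self, k_candidates=tuple(range(2, 10)), n_init: int = 10,
                 random_state: int = 0):
        self.k_candidates = k_candidates
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        candidates = sorted(int(k) for k in self.k_candidates)
        if any(k < 2 for k in candidates):
            raise ValueError("all k candidates must be >= 2")
        if max(candidates) >= len(X):
            raise ValueError("fewer voxels than the largest candidate k")
        self.ch_scores_ = {}
        best = None
        for k in candidates:
            km = KMeans(n_clusters=k, n_init=self.n_init, init="k-means++",
                        random_state=self.random_state).fit(X)
            score = calinski_harabasz(X, km.labels_)
            self.ch_scores_[k] = score
            if best is None or score > best[0]:
                best = (score, k, km)
        _, self.k_, km = best
        # canonical habitat order: ascending mean arterial (column 0) centroid
        order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
        self.order_ = order
        self.cluster_centers_ = km.cluster_centers_[order]
        relabel = np.empty_like(order)
        relabel[order] = np.arange(self.k_)
        self.labels_ = relabel[km.labels_]
        self.inertia_ = km.inertia_
        return self

    def predict(self, X):
        """Nearest-centroid labels (0-based; ties -> lowest canonical id)."""
        check_is_fitted(self, "cluster_centers_")
        d = cdist(np.asarray(X, dtype=np.float64), self.cluster_centers_)
        return d.argmin(axis=1)


def select_k_and_fit(space: VoxelFeatureSpace, k_candidates=tuple(range(2, 10)),
                     n_init: int = 10, seed: int = 0) -> HabitatClusterer:
    """Convenience wrapper: fit a :class:`HabitatClusterer` on a voxel space."""
    return HabitatClusterer(k_candidates=k_candidates, n_init=n_init,
                            random_state=seed).fit(space.X)


@dataclass
class HabitatLabeling:
    """Per-patient habitat label volumes (ids 1..k inside mask, 0 outside)."""

    label_volumes: dict = field(default_factory=dict)
    proportions: pd.DataFrame | None = None       # patients x habitats, fractions
    cohort_proportions: pd.Series | None = None   # pooled over all masked voxels


def assign_habitats(model: HabitatClusterer, maps_by_patient: dict[object, EnhancementMaps],
                    transform: ZScoreTransform) -> HabitatLabeling:
    """Label every masked voxel of every patient by nearest centroid.

    Voxels are standardised with the derivation-pool transform before
    assignment.  Habitat ids are 1-based in the label volumes; proportions
    are computed per patient and pooled over the cohort.
    """
    check_is_fitted(model, "cluster_centers_")
    out = HabitatLabeling()
    rows = {}
    counts_total = np.zeros(model.k_)
    for pid, maps in maps_by_patient.items():
        vecs, lin = _masked_vectors(maps)
        labels = model.predict(transform.apply(vecs)) + 1
        vol = np.zeros(maps.mask.data.shape, dtype=np.int32)
        vol.reshape(-1)[lin] = labels
        out.label_volumes[pid] = vol
        counts = np.bincount(labels - 1, minlength=model.k_).astype(float)
        counts_total += counts
        rows[pid] = counts / counts.sum()
    cols = [f"habitat_{h}" for h in range(1, model.k_ + 1)]
    out.proportions = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    out.cohort_proportions = pd.Series(counts_total / counts_total.sum(), index=cols)
    return out
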