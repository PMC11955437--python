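"""IBSI-style texture feature extraction for tumor and habitat regions.

Implements the image filters, intensity discretisation and feature classes
behind names like ``Enhanced_D_habitat2_binomialblur1_ngtdm_Contrast``:

* ``binomial_blur`` — separable [1, 2, 1]/4 smoothing kernel applied per
  axis with clamp-to-edge handling, repeated r times (the
  ``binomialblurimage`` filter family);
* fixed-bin-count / fixed-bin-width discretisation;
* first-order statistics (18 features), grey-level co-occurrence (GLCM),
  grey-level run-length (GLRLM), grey-level size-zone (GLSZM),
  neighbourhood grey-tone difference (NGTDM), grey-level dependence
  (GLDM), and mask shape descriptors.

All matrix classes use 3-D aggregation: 26-connected neighbourhoods and the
13 unique distance-1 directions, restricted to in-mask voxels.  Feature
names follow ``{sequence}_{region}_{filter}_{class}_{Feature}``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: the 13 unique 3-D directions at Chebyshev distance 1 (half of the
#: 26-neighbourhood; the other half are their negations).
DIRECTIONS_13 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]
OFFSETS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]

FEATURE_CLASSES = ("firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")


@dataclass(frozen=True)
class FeatureSpec:
    """One (filter, feature class, discretisation) extraction cell."""

    filter: str = "original"            # "original" or "binomialblur<r>"
    feature_class: str = "firstorder"
    n_bins: int = 32                    # fixed-bin-count discretisation
    bin_width: float | None = None      # overrides n_bins when set

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.bin_width is not None:
            if self.bin_width <= 0:
                raise ValueError("bin_width must be > 0")
        elif self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.filter != "original":
            if not self.filter.startswith("binomialblur") or int(self.filter[12:]) < 1:
                raise ValueError(f"unknown filter {self.filter!r}")


def default_feature_specs(classes=FEATURE_CLASSES,
                          filters=("original", "binomialblur1", "binomialblur2"),
                          n_bins: int = 32) -> list[FeatureSpec]:
    return [FeatureSpec(filter=f, feature_class=c, n_bins=n_bins)
            for f in filters for c in classes]


# ---------------------------------------------------------------------------
# Filters and discretisation
# ---------------------------------------------------------------------------

def binomial_blur(volume: np.ndarray, repetitions: int = 1) -> np.ndarray:
    """Apply the separable binomial [1,2,1]/4 kernel per axis, r times.

    Edge handling replicates the border voxel (clamp-to-edge); r
    repetitions are exactly the r-fold composition of a single pass.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    out = np.asarray(volume, dtype=np.float64)
    kernel = np.array([0.25, 0.5, 0.25])
    for _ in range(repetitions):
        for axis in range(out.ndim):
            out = ndimage.correlate1d(out, kernel, axis=axis, mode="nearest")
    return out


def apply_filter(volume: np.ndarray, name: str) -> np.ndarray:
    if name == "original":
        return np.asarray(volume, dtype=np.float64)
    return binomial_blur(volume, int(name[len("binomialblur"):]))


def discretize(volume: np.ndarray, mask: np.ndarray, n_bins: int | None = 32,
               bin_width: float | None = None) -> np.ndarray:
    """Map in-mask intensities to integer levels 1..n (0 outside the mask).

    Fixed bin count: equal-width bins spanning [min, max] inside the mask,
    with the maximum mapped into the top bin; a constant region maps to
    level 1.  Fixed bin width w: level = floor((x - min)/w) + 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.asarray(volume, dtype=np.float64)
    inside = vals[mask]
    levels = np.zeros(vals.shape, dtype=np.int64)
    lo, hi = inside.min(), inside.max()
    if bin_width is not None:
        levels[mask] = np.floor((inside - lo) / bin_width).astype(np.int64) + 1
    else:
        if hi == lo:
            levels[mask] = 1
        else:
            # right-inclusive equal-width bins: a value on an interior edge
            # belongs to the lower bin, the minimum maps to level 1.
            width = (hi - lo) / n_bins
            levels[mask] = np.maximum(
                np.ceil((inside - lo) / width).astype(np.int64), 1)
    return levels


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------

def first_order_features(volume: np.ndarray, mask: np.ndarray, n_bins: int = 32,
                         voxel_volume: float = 1.0) -> dict[str, float]:
    """The 18 standard first-order features of the in-mask intensities.

    Entropy and Uniformity are computed on the fixed-bin-count histogram;
    a constant region has entropy 0 and uniformity 1.
    """
    x = np.asarray(volume, dtype=np.float64)[np.asarray(mask, dtype=bool)]
    n = x.size
    mean = x.mean()
    var = x.var()               # population variance
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    levels = discretize(x.reshape(-1, 1, 1), np.ones((n, 1, 1), dtype=bool), n_bins=n_bins)
    counts = np.bincount(levels.reshape(-1))[1:]
    p = counts[counts > 0] / n
    robust = x[(x >= p10) & (x <= p90)]
    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd ** 3)
        kurt = float(((x - mean) ** 4).mean() / sd ** 4)
    else:
        skew, kurt = 0.0, 0.0
    energy = float((x ** 2).sum())
    return {
        "Mean": float(mean),
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "InterquartileRange": float(p75 - p25),
        "Variance": float(var),
        "Skewness": skew,
        "Kurtosis": kurt,
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation":
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Uniformity": float((p ** 2).sum()),
    }


# ---------------------------------------------------------------------------
# Shared helpers for matrix classes
# ---------------------------------------------------------------------------

def _shift_pairs(levels: np.ndarray, mask: np.ndarray, offset) -> tuple[np.ndarray, np.ndarray]:
    """Return level pairs (a, b) for all in-mask voxel pairs related by offset."""
    sl_a, sl_b = [], []
    for o, size in zip(offset, levels.shape):
        if o >= 0:
            sl_a.append(slice(0, size - o))
            sl_b.append(slice(o, size))
        else:
            sl_a.append(slice(-o, size))
            sl_b.append(slice(0, size + o))
    a, b = levels[tuple(sl_a)], levels[tuple(sl_b)]
    m = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    return a[m], b[m]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(levels: np.ndarray, mask: np.ndarray, offset) -> np.ndarray:
    """Symmetric normalised co-occurrence matrix for one offset (or None if
    the offset produces no in-mask pairs)."""
    n_levels = int(levels[mask].max())
    a, b = _shift_pairs(levels, mask, offset)
    if a.size == 0:
        return None
    P = np.zeros((n_levels, n_levels))
    np.add.at(P, (a - 1, b - 1), 1.0)
    P = P + P.T
    return P / P.sum()


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    n = P.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    diff = np.abs(ii - jj)
    k_diff = np.arange(0, n)
    p_diff = np.array([P[diff == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * n + 1)
    p_sum = np.array([P[(ii + jj) == k].sum() for k in k_sum])
    nz = P > 0
    ent = float(-(P[nz] * np.log2(P[nz])).sum())
    da = float((k_diff * p_diff).sum())
    pd_nz = p_diff > 0
    ps_nz = p_sum > 0
    corr = float(((ii * jj * P).sum() - mu ** 2) / sigma2) if sigma2 > 0 else 1.0
    off_diag = diff > 0
    return {
        "Autocorrelation": float((ii * jj * P).sum()),
        "JointAverage": mu,
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * P).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * P).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * P).sum()),
        "Contrast": float((diff ** 2 * P).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff[pd_nz] * np.log2(p_diff[pd_nz])).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Dissimilarity": float((diff * P).sum()),
        "Energy": float((P ** 2).sum()),
        "JointEntropy": ent,
        "Homogeneity": float((P / (1.0 + diff ** 2)).sum()),
        "InverseDifference": float((P / (1.0 + diff)).sum()),
        "InverseVariance": float((P[off_diag] / diff[off_diag] ** 2).sum()),
        "MaximumProbability": float(P.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[ps_nz] * np.log2(p_sum[ps_nz])).sum()),
        "SumSquares": sigma2,
    }


def glcm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """GLCM features averaged over the 13 distance-1 offsets."""
    mask = np.asarray(mask, dtype=bool)
    per_offset = []
    for off in DIRECTIONS_13:
        P = glcm_matrix(levels, mask, off)
        if P is not None:
            per_offset.append(_glcm_features_single(P))
    if not per_offset:
        # single-voxel region: no pairs at all
        keys = _glcm_features_single(np.array([[1.0]])).keys()
        return {k: 0.0 for k in keys}
    keys = per_offset[0].keys()
    return {k: float(np.mean([f[k] for f in per_offset])) for k in keys}


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_matrix(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Neighbourhood grey-tone difference table.

    Returns ``(n_i, s_i, n_valid)`` indexed by level 1..max: voxel counts,
    summed absolute differences from the mean of the 26-connected in-mask
    neighbourhood, and the number of voxels with at least one in-mask
    neighbour.
    """
    mask = np.asarray(mask, dtype=bool)
    lv = np.asarray(levels, dtype=np.float64) * mask
    neighbor_sum = np.zeros(lv.shape)
    neighbor_cnt = np.zeros(lv.shape)
    for off in OFFSETS_26:
        dst, src = [], []
        for o, size in zip(off, lv.shape):
            if o >= 0:
                dst.append(slice(0, size - o))
                src.append(slice(o, size))
            else:
                dst.append(slice(-o, size))
                src.append(slice(0, size + o))
        dst, src = tuple(dst), tuple(src)
        neighbor_sum[dst] += lv[src]
        neighbor_cnt[dst] += mask[src]
    valid = mask & (neighbor_cnt > 0)
    n_levels = int(levels[mask].max())
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    lab = levels[valid]
    diffs = np.abs(levels[valid] - neighbor_sum[valid] / neighbor_cnt[valid])
    np.add.at(n_i, lab - 1, 1.0)
    np.add.at(s_i, lab - 1, diffs)
    return n_i, s_i, int(valid.sum())


def ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity, Strength (IBSI forms).

    Contrast follows
    ``[1/(Ngp(Ngp-1)) sum_ij p_i p_j (i-j)^2] * [(1/Nv) sum_i s_i]`` over
    occupied levels; with a single occupied level it is defined as 0.
    Coarseness of a perfectly flat region is capped at 1e6.
    """
    n_i, s_i, n_valid = ngtdm_matrix(levels, mask)
    if n_valid == 0:
        return {"Coarseness": 1e6, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    occ = np.flatnonzero(n_i > 0)
    p = n_i / n_valid
    i_lv = np.arange(1, len(n_i) + 1, dtype=np.float64)
    ngp = occ.size
    ps = float((p * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6

    contrast = 0.0
    busyness = 0.0
    complexity = 0.0
    strength = 0.0
    if ngp > 1:
        pi, pj = np.meshgrid(p[occ], p[occ], indexing="ij")
        li, lj = np.meshgrid(i_lv[occ], i_lv[occ], indexing="ij")
        si, sj = np.meshgrid(s_i[occ], s_i[occ], indexing="ij")
        contrast = float((pi * pj * (li - lj) ** 2).sum() / (ngp * (ngp - 1))
                         * s_i.sum() / n_valid)
        denom = float(np.abs(li * pi - lj * pj)[li != lj].sum())
        busyness = ps / denom if denom > 0 else 0.0
        complexity = float((np.abs(li - lj) * (pi * si + pj * sj) / (pi + pj)).sum()
                           / n_valid)
        s_total = float(s_i.sum())
        strength = float(((pi + pj) * (li - lj) ** 2).sum() / s_total) if s_total > 0 else 0.0
    return {"Coarseness": min(coarseness, 1e6), "Contrast": contrast,
            "Busyness": busyness, "Complexity": complexity, "Strength": strength}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, direction) -> np.ndarray:
    """Run-length matrix (levels x run-lengths) for one direction.

    Runs are maximal sequences of equal-level in-mask voxels along the
    direction; out-of-mask voxels break runs.
    """
    mask = np.asarray(mask, dtype=bool)
    n_levels = int(levels[mask].max())
    shape = levels.shape
    d = np.asarray(direction)
    coords = np.argwhere(mask)
    voxset = {tuple(c): int(levels[tuple(c)]) for c in coords}
    counts: dict[tuple[int, int], int] = {}
    max_len = 1
    for c in coords:
        c = tuple(c)
        prev = tuple(np.asarray(c) - d)
        if prev in voxset and voxset[prev] == voxset[c]:
            continue  # not a run start
        length = 1
        cur = tuple(np.asarray(c) + d)
        while cur in voxset and voxset[cur] == voxset[c]:
            length += 1
            cur = tuple(np.asarray(cur) + d)
        key = (voxset[c], length)
        counts[key] = counts.get(key, 0) + 1
        max_len = max(max_len, length)
    R = np.zeros((n_levels, max_len))
    for (lvl, length), cnt in counts.items():
        R[lvl - 1, length - 1] = cnt
    return R


def _rl_features(R: np.ndarray, n_voxels: int, prefix_short="Run") -> dict[str, float]:
    """Shared run-length / zone-size feature formulas on a levels x sizes matrix."""
    n_runs = R.sum()
    i = np.arange(1, R.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, R.shape[1] + 1, dtype=np.float64)[None, :]
    p = R / n_runs
    pg = R.sum(axis=1)
    pr = R.sum(axis=0)
    mu_i = float((i[:, 0] * pg).sum() / n_runs)
    mu_j = float((j[0] * pr).sum() / n_runs)
    nz = p > 0
    return {
        f"Short{prefix_short}Emphasis": float((R / j ** 2).sum() / n_runs),
        f"Long{prefix_short}Emphasis": float((R * j ** 2).sum() / n_runs),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / n_runs),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum() / n_runs ** 2),
        f"{prefix_short}LengthNonUniformity": float((pr ** 2).sum() / n_runs),
        f"{prefix_short}LengthNonUniformityNormalized": float((pr ** 2).sum() / n_runs ** 2),
        f"{prefix_short}Percentage": float(n_runs / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        f"{prefix_short}LengthVariance": float((p * (j - mu_j) ** 2).sum()),
        f"{prefix_short}Entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelEmphasis": float((R / i ** 2).sum() / n_runs),
        "HighGrayLevelEmphasis": float((R * i ** 2).sum() / n_runs),
        f"Short{prefix_short}LowGrayLevelEmphasis": float((R / (i ** 2 * j ** 2)).sum() / n_runs),
        f"Short{prefix_short}HighGrayLevelEmphasis": float((R * i ** 2 / j ** 2).sum() / n_runs),
        f"Long{prefix_short}LowGrayLevelEmphasis": float((R * j ** 2 / i ** 2).sum() / n_runs),
        f"Long{prefix_short}HighGrayLevelEmphasis": float((R * i ** 2 * j ** 2).sum() / n_runs),
    }


def glrlm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Run-length features averaged over the 13 directions."""
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    per_dir = [_rl_features(glrlm_matrix(levels, mask, d), n_vox, "Run")
               for d in DIRECTIONS_13]
    keys = per_dir[0].keys()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in keys}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_matrix(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Size-zone matrix: 26-connected zones of equal level (levels x sizes)."""
    mask = np.asarray(mask, dtype=bool)
    n_levels = int(levels[mask].max())
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    max_size = 1
    for lvl in range(1, n_levels + 1):
        region = (levels == lvl) & mask
        if not region.any():
            continue
        lab, n_zones = ndimage.label(region, structure=structure)
        sizes = np.bincount(lab.reshape(-1))[1:]
        for s in sizes:
            zones[(lvl, int(s))] = zones.get((lvl, int(s)), 0) + 1
            max_size = max(max_size, int(s))
    Z = np.zeros((n_levels, max_size))
    for (lvl, size), cnt in zones.items():
        Z[lvl - 1, size - 1] = cnt
    return Z


def glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    feats = _rl_features(glszm_matrix(levels, mask), int(mask.sum()), "Zone")
    # rename the Short/Long pair to the conventional Small/Large Area wording
    renames = {k: k.replace("ShortZone", "SmallArea").replace("LongZone", "LargeArea")
               for k in feats if "ShortZone" in k or "LongZone" in k}
    return {renames.get(k, k): v for k, v in feats.items()}


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(levels: np.ndarray, mask: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Dependence matrix: levels x dependence counts.

    A voxel's dependence is 1 (itself) plus the number of 26-connected
    in-mask neighbours whose level differs by at most ``alpha``.
    """
    mask = np.asarray(mask, dtype=bool)
    n_levels = int(levels[mask].max())
    dep = np.zeros(levels.shape)
    for off in OFFSETS_26:
        sl_a, sl_b = [], []
        for o, size in zip(off, levels.shape):
            if o >= 0:
                sl_a.append(slice(0, size - o))
                sl_b.append(slice(o, size))
            else:
                sl_a.append(slice(-o, size))
                sl_b.append(slice(0, size + o))
        close = (np.abs(levels[tuple(sl_a)] - levels[tuple(sl_b)]) <= alpha) \
            & mask[tuple(sl_a)] & mask[tuple(sl_b)]
        dep[tuple(sl_a)] += close
    dmax = int(dep[mask].max()) + 1
    D = np.zeros((n_levels, dmax))
    np.add.at(D, (levels[mask] - 1, dep[mask].astype(np.int64)), 1.0)
    return D


def gldm_features(levels: np.ndarray, mask: np.ndarray, alpha: int = 0) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    feats = _rl_features(gldm_matrix(levels, mask, alpha), int(mask.sum()), "Dependence")
    renames = {k: k.replace("ShortDependence", "SmallDependence")
                .replace("LongDependence", "LargeDependence") for k in feats}
    return {renames.get(k, k): v for k, v in feats.items()}


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

def shape_features(mask: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """Mesh-free 3-D shape descriptors of the binary mask."""
    mask = np.asarray(mask, dtype=bool)
    vs = np.asarray(voxel_size, dtype=np.float64)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask is empty")
    voxel_vol = float(vs.prod())
    volume = n * voxel_vol
    # surface area: exposed voxel faces per axis
    area = 0.0
    face_areas = [vs[1] * vs[2], vs[0] * vs[2], vs[0] * vs[1]]
    for axis in range(3):
        padded = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        exposed = np.abs(np.diff(padded.astype(np.int8), axis=axis)).sum()
        area += exposed * face_areas[axis]
    sphericity = (np.pi ** (1 / 3)) * (6 * volume) ** (2 / 3) / area
    coords = np.argwhere(mask) * vs
    # maximum 3-D diameter over surface voxels (subsampled if very large)
    eroded = ndimage.binary_erosion(mask)
    surf = np.argwhere(mask & ~eroded) * vs
    if len(surf) > 2000:
        surf = surf[np.linspace(0, len(surf) - 1, 2000).astype(int)]
    if len(surf) >= 2:
        from scipy.spatial.distance import pdist
        max_diam = float(pdist(surf).max())
    else:
        max_diam = float(vs.max())
    if n > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        eig = np.clip(eig, 0, None)
        major, minor, least = 4.0 * np.sqrt(eig)
        elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
        flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0
    else:
        major = minor = least = 0.0
        elongation = flatness = 1.0
    return {"VoxelVolume": volume, "SurfaceArea": float(area),
            "Sphericity": float(sphericity),
            "SurfaceVolumeRatio": float(area / volume),
            "Maximum3DDiameter": max_diam,
            "MajorAxisLength": float(major), "MinorAxisLength": float(minor),
            "LeastAxisLength": float(least),
            "Elongation": elongation, "Flatness": flatness}


# ---------------------------------------------------------------------------
# Extraction orchestrator
# ---------------------------------------------------------------------------

_CLASS_NEEDS_LEVELS = {"glcm": glcm_features, "glrlm": glrlm_features,
                       "glszm": glszm_features, "ngtdm": ngtdm_features,
                       "gldm": gldm_features}


def extract_features(volumes: dict[str, np.ndarray], regions: dict[str, np.ndarray],
                     specs: list[FeatureSpec], voxel_size=(1.0, 1.0, 1.0),
                     include_shape: bool = True) -> dict[str, float]:
    """Extract the full named feature vector for one patient.

    ``volumes`` maps sequence names (e.g. ``T1_A``, ``Enhanced_D``) to 3-D
    arrays; ``regions`` maps region names (``tumor``, ``habitat1`` ...) to
    boolean masks.  An empty region yields NaN for every one of its
    features (missing, to be imputed downstream, never zero).  Shape
    features are computed on non-empty regions once (intensity-independent).
    """
    voxel_vol = float(np.prod(voxel_size))
    out: dict[str, float] = {}
    for region_name, region in regions.items():
        region = np.asarray(region, dtype=bool)
        empty = not region.any()
        filtered_cache: dict[str, np.ndarray] = {}
        for seq_name, vol in volumes.items():
            for spec in specs:
                prefix = f"{seq_name}_{region_name}_{spec.filter}_{spec.feature_class}"
                if empty:
                    feats = {k: np.nan for k in _feature_names_for(spec)}
                else:
                    key = f"{seq_name}|{spec.filter}"
                    if key not in filtered_cache:
                        filtered_cache[key] = apply_filter(vol, spec.filter)
                    fv = filtered_cache[key]
                    if spec.feature_class == "firstorder":
                        feats = first_order_features(fv, region, n_bins=spec.n_bins,
                                                     voxel_volume=voxel_vol)
                    else:
                        levels = discretize(fv, region, n_bins=spec.n_bins,
                                            bin_width=spec.bin_width)
                        feats = _CLASS_NEEDS_LEVELS[spec.feature_class](levels, region)
                out.update({f"{prefix}_{k}": v for k, v in feats.items()})
        if include_shape:
            if empty:
                names = shape_features(np.ones((2, 2, 2), dtype=bool)).keys()
                out.update({f"{region_name}_shape_{k}": np.nan for k in names})
            else:
                out.update({f"{region_name}_shape_{k}": v
                            for k, v in shape_features(region, voxel_size).items()})
    return out


_NAME_CACHE: dict[str, list[str]] = {}


def _feature_names_for(spec: FeatureSpec) -> list[str]:
    """Feature names a class produces (computed once on a tiny probe volume)."""
    if spec.feature_class not in _NAME_CACHE:
        probe = np.arange(8, dtype=np.float64).reshape(2, 2, 2)
        pmask = np.ones((2, 2, 2), dtype=bool)
        if spec.feature_class == "firstorder":
            names = list(first_order_features(probe, pmask).keys())
        else:
            lv = discretize(probe, pmask, n_bins=4)
            names = list(_CLASS_NEEDS_LEVELS[spec.feature_class](lv, pmask).keys())
        _NAME_CACHE[spec.feature_class] = names
    return _NAME_CACHE[spec.feature_class]
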