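"""Volume I/O, grid harmonisation, and enhancement-ratio parametric maps.

Multiphase T1 studies (pre-contrast, arterial, venous, delayed) are loaded
from NIfTI, reoriented to a canonical axis order, and resampled onto the
pre-contrast grid (trilinear for images, nearest-neighbour for the tumor
mask).  From a harmonised :class:`PhaseSet` three voxelwise enhancement maps
are derived — Enhanced_A, Enhanced_V, Enhanced_D — either as a ratio

    E = (S_phase - S_pre) / (S_pre + eps)

or as a plain difference ``E = S_phase - S_pre``.  Both conventions are
provided because signal-enhancement-ratio maps are variously reported either
way in the contrast-enhanced MRI literature; the ratio form is the default
as it normalises inter-scanner signal scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage


class InputError(ValueError):
    """Raised for unusable inputs (missing phase, empty mask, bad file)."""


class DegenerateChannelError(ValueError):
    """Raised when a channel is constant inside the mask and cannot be z-scored."""


@dataclass
class VolumeGrid:
    """A 3-D scalar field with voxel size and a NIfTI-style affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise InputError(f"volume must be 3-D with positive shape, got {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise InputError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths in mm per axis, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class PhaseSet:
    """Co-registered multiphase volumes plus a binary tumor mask.

    All members share grid shape and affine; the mask must contain at least
    one foreground voxel.
    """

    pre: VolumeGrid
    arterial: VolumeGrid
    venous: VolumeGrid
    delayed: VolumeGrid
    mask: VolumeGrid
    t2: VolumeGrid | None = None
    dwi: VolumeGrid | None = None

    def __post_init__(self) -> None:
        ref = self.pre
        for name, vol in self.volumes().items():
            if vol.shape != ref.shape:
                raise InputError(f"phase '{name}' shape {vol.shape} != pre shape {ref.shape}")
        m = self.mask.data
        if not np.isin(m, (0.0, 1.0)).all():
            raise InputError("mask must be binary")
        if m.sum() < 1:
            raise InputError("mask is empty: no tumor voxels")

    def volumes(self) -> dict[str, VolumeGrid]:
        out = {"pre": self.pre, "arterial": self.arterial, "venous": self.venous,
               "delayed": self.delayed, "mask": self.mask}
        if self.t2 is not None:
            out["t2"] = self.t2
        if self.dwi is not None:
            out["dwi"] = self.dwi
        return out

    @property
    def mask_bool(self) -> np.ndarray:
        return self.mask.data > 0.5


@dataclass
class EnhancementMaps:
    """The three enhancement maps derived from a PhaseSet (dimensionless in
    ratio mode, signal units in difference mode)."""

    enhanced_a: VolumeGrid
    enhanced_v: VolumeGrid
    enhanced_d: VolumeGrid
    mode: str
    epsilon: float
    mask: VolumeGrid

    def as_dict(self) -> dict[str, VolumeGrid]:
        return {"Enhanced_A": self.enhanced_a, "Enhanced_V": self.enhanced_v,
                "Enhanced_D": self.enhanced_d}


# ---------------------------------------------------------------------------
# NIfTI I/O and resampling
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> VolumeGrid:
    """Load a NIfTI volume, reoriented to the closest canonical (RAS) axes."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    img = nib.as_closest_canonical(nib.load(str(p)))
    return VolumeGrid(np.asarray(img.get_fdata(), dtype=np.float64), img.affine)


def write_volume(vol: VolumeGrid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def resample_to(vol: VolumeGrid, reference: VolumeGrid, order: int = 1) -> VolumeGrid:
    """Resample ``vol`` onto ``reference``'s grid (order 1 trilinear, 0 nearest).

    Resampling a volume onto its own grid is the identity.
    """
    if vol.shape == reference.shape and np.allclose(vol.affine, reference.affine):
        return VolumeGrid(vol.data.copy(), reference.affine.copy())
    # index_src = A_src^-1 @ A_ref @ index_ref
    matrix = np.linalg.inv(vol.affine) @ reference.affine
    out = ndimage.affine_transform(
        vol.data, matrix[:3, :3], offset=matrix[:3, 3],
        output_shape=reference.shape, order=order, mode="nearest")
    return VolumeGrid(out, reference.affine.copy())


def read_phase_set(paths: Mapping[str, str | Path]) -> PhaseSet:
    """Load a multiphase study from NIfTI files keyed by phase name.

    Required keys: ``pre``, ``arterial``, ``venous``, ``delayed``, ``mask``;
    optional: ``t2``, ``dwi``.  Everything is resampled onto the pre-contrast
    grid (images trilinear, mask nearest-neighbour then thresholded at 0.5).
    """
    required = ("pre", "arterial", "venous", "delayed", "mask")
    missing = [k for k in required if k not in paths]
    if missing:
        raise InputError(f"missing phase path(s): {missing}")
    pre = read_volume(paths["pre"])
    vols: dict[str, VolumeGrid] = {"pre": pre}
    for key in ("arterial", "venous", "delayed", "t2", "dwi"):
        if key in paths and paths[key] is not None:
            vols[key] = resample_to(read_volume(paths[key]), pre, order=1)
    mask_raw = resample_to(read_volume(paths["mask"]), pre, order=0)
    mask = VolumeGrid((mask_raw.data > 0.5).astype(np.float64), pre.affine.copy())
    if mask.data.sum() < 1:
        raise InputError("mask is empty: no tumor voxels")
    return PhaseSet(pre=pre, arterial=vols["arterial"], venous=vols["venous"],
                    delayed=vols["delayed"], mask=mask,
                    t2=vols.get("t2"), dwi=vols.get("dwi"))


def write_phase_set(ps: PhaseSet, directory: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write each phase and the mask as ``<prefix><name>.nii.gz``; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for name, vol in ps.volumes().items():
        path = directory / f"{prefix}{name}.nii.gz"
        write_volume(vol, path)
        out[name] = path
    return out


# ---------------------------------------------------------------------------
# Enhancement maps
# ---------------------------------------------------------------------------

def compute_enhancement_maps(ps: PhaseSet, mode: str = "ratio",
                             epsilon: float | None = None) -> EnhancementMaps:
    """Derive Enhanced_A/V/D maps from a PhaseSet.

    ``mode='ratio'`` gives ``(S_phase - S_pre) / (S_pre + epsilon)``;
    ``mode='difference'`` gives ``S_phase - S_pre``.  When ``epsilon`` is
    None in ratio mode it defaults to 1e-6 times the mean pre-contrast
    signal inside the mask, which keeps ratios finite on near-zero voxels
    without perturbing typical tissue values.
    """
    if mode not in ("ratio", "difference"):
        raise ValueError(f"mode must be 'ratio' or 'difference', got {mode!r}")
    mask = ps.mask_bool
    pre = ps.pre.data
    if mode == "ratio":
        if epsilon is None:
            epsilon = 1e-6 * float(np.abs(pre[mask]).mean())
        if epsilon <= 0 and np.any(pre[mask] == 0):
            raise FloatingPointError(
                "ratio mode with epsilon <= 0 and zero-valued pre-contrast voxels inside mask")
        denom = pre + epsilon
    else:
        epsilon = 0.0
        denom = None

    def _one(phase: VolumeGrid) -> VolumeGrid:
        diff = phase.data - pre
        data = diff / denom if denom is not None else diff
        if not np.isfinite(data[mask]).all():
            raise FloatingPointError("non-finite enhancement values inside mask")
        return VolumeGrid(data, ps.pre.affine.copy())

    return EnhancementMaps(_one(ps.arterial), _one(ps.venous), _one(ps.delayed),
                           mode=mode, epsilon=float(epsilon), mask=ps.mask)


# ---------------------------------------------------------------------------
# Masked z-scoring
# ---------------------------------------------------------------------------

@dataclass
class ZScoreTransform:
    """Per-channel standardisation parameters (population-sd convention).

    The population (1/n) denominator is used for the sd; the same transform
    object is reused to standardise held-out patients so derivation and
    validation data share one scale.
    """

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=np.float64) - self.mean) / self.sd


def zscore_within_mask(values: np.ndarray, mask: np.ndarray | None = None
                       ) -> tuple[np.ndarray, ZScoreTransform]:
    """Standardise values (n x c matrix or a masked 3-D field) to mean 0, sd 1.

    Returns the standardised values and the fitted :class:`ZScoreTransform`.
    Raises :class:`DegenerateChannelError` naming any constant channel.
    """
    values = np.asarray(values, dtype=np.float64)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    flat = values.reshape(len(values), -1) if values.ndim > 1 else values.reshape(-1, 1)
    if len(flat) < 2:
        raise InputError("need at least 2 voxels inside the mask to z-score")
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)  # population denominator
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateChannelError(f"constant channel(s) {bad.tolist()} cannot be z-scored")
    transform = ZScoreTransform(mean=mean, sd=sd)
    standardized = transform.apply(flat)
    return standardized.reshape(values.shape), transform
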