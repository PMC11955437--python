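import numpy as np
import pytest

from habitatmri.imaging import PhaseSet, VolumeGrid
from habitatmri.synth import SynthVolumeSpec, VoxelMixtureSpec, generate_multiphase_study


@pytest.fixture
def separated_mixture():
    """Well-separated 3-component mixture at the study's habitat weights."""
    return VoxelMixtureSpec(n_components=3, weights=(0.163, 0.464, 0.373),
                            sigma=0.05, n_voxels=30_000, seed=11)


@pytest.fixture
def small_phase_set():
    """A noiseless single-habitat phantom with known enhancement ratios."""
    spec = SynthVolumeSpec(
        grid_shape=(12, 12, 12), tumor_radius=4.0, noise_sd=0.0,
        mixture=VoxelMixtureSpec(n_components=1, weights=(1.0,),
                                 means=((0.5, 1.0, 0.8),), sigma=1e-12,
                                 n_voxels=1, seed=0),
        seed=0)
    ps, habitats = generate_multiphase_study(spec)
    return ps, habitats


def make_phase_set(pre, arterial, venous, delayed, mask, affine=None):
    affine = np.eye(4) if affine is None else affine
    return PhaseSet(pre=VolumeGrid(pre, affine), arterial=VolumeGrid(arterial, affine),
                    venous=VolumeGrid(venous, affine), delayed=VolumeGrid(delayed, affine),
                    mask=VolumeGrid(mask.astype(float), affine))
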