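"""Shared fixtures: small noise-free phantoms reused across test modules."""

import numpy as np
import pytest

from synapsekin.core import VolumeSeries
from synapsekin.phantom import PhantomParams, generate_doublet


@pytest.fixture(scope="session")
def doublet():
    """Noise-free default-geometry doublet movie with ground truth."""
    params = PhantomParams(n_frames=4, seed=7)
    series, truth = generate_doublet(params)
    return params, series, truth


@pytest.fixture(scope="session")
def doublet_iso():
    """Isotropic-voxel doublet (what the advanced organelle analyses use)."""
    params = PhantomParams(
        n_frames=4,
        grid_shape=(42, 64, 64),
        voxel_size=(0.35, 0.35, 0.35),
        droplet_center=(7.35, 11.2, 6.5),
        cell_center=(7.35, 11.2, 16.5),
        seed=11,
    )
    series, truth = generate_doublet(params)
    return params, series, truth


def make_series(data, voxel_size=(1.0, 1.0, 1.0), frame_interval=30.0, names=None):
    data = np.asarray(data, float)
    if names is None:
        names = tuple(f"ch{i}" for i in range(data.shape[1]))
    return VolumeSeries(data, voxel_size, frame_interval, names)
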