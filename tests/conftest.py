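"""Shared builders for in-memory grids, maps and series."""

import numpy as np
import pytest

from comet.volume_io import BrainMask, ScalarMap, VolumeGrid
from comet.preprocess import BoldSeries


def grid_and_mask(dims):
    grid = VolumeGrid.isotropic(dims)
    return grid, BrainMask(grid, np.ones(dims, dtype=bool))


def scalar_map(values, dims=None, tag="raw"):
    """ScalarMap over a fully in-mask grid holding the given flat values."""
    values = np.asarray(values, dtype=float)
    if dims is None:
        dims = (values.size, 1, 1)
    grid, mask = grid_and_mask(dims)
    return ScalarMap(grid, mask, values.reshape(-1), tag)


def bold_series(data, tr=1.5, dims=None):
    """BoldSeries from an (n_vox, n_frames) array on a fully in-mask grid."""
    data = np.asarray(data, dtype=float)
    if dims is None:
        dims = (data.shape[0], 1, 1)
    grid, mask = grid_and_mask(dims)
    return BoldSeries(grid, mask, data, tr)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
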