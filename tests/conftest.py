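import numpy as np
import pytest

from dynecm.io_volumes import AnalysisMask, MaskedSeries, VolumeGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return VolumeGeometry(shape=(6, 6, 6), affine=np.eye(4))


@pytest.fixture
def full_mask(geometry):
    """Mask covering the whole 6x6x6 grid."""
    idx = np.argwhere(np.ones(geometry.shape, dtype=bool))
    return AnalysisMask(geometry=geometry, voxel_indices=idx)


def make_series(rng, n_voxels=20, T=50, tr=2.0):
    """Random MaskedSeries on a minimal grid holding n_voxels voxels."""
    side = int(np.ceil(n_voxels ** (1 / 3))) + 1
    geom = VolumeGeometry(shape=(side, side, side), affine=np.eye(4))
    all_idx = np.argwhere(np.ones(geom.shape, dtype=bool))
    mask = AnalysisMask(geometry=geom, voxel_indices=all_idx[:n_voxels])
    data = rng.standard_normal((n_voxels, T))
    return MaskedSeries(mask=mask, data=data, tr_seconds=tr)


@pytest.fixture
def series_factory():
    return make_series
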