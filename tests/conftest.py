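import numpy as np
import pytest

from netqual.pipeline import RegionalSignalMatrix
from netqual.synthetic import GroupSpec, LatentNetwork, VolumeLayout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_layout():
    """Tiny volume for fast subject generation (128 interior voxels)."""
    return VolumeLayout(shape=(12, 12, 6), air_margin=2)


@pytest.fixture
def three_region_latent():
    """Two regions coupled through a common third: r(0,1) > 0."""
    c = np.zeros((3, 3))
    c[0, 2] = c[2, 0] = 0.8
    c[1, 2] = c[2, 1] = 0.8
    return LatentNetwork(coupling=c)


@pytest.fixture
def quiet_spec():
    """Small fixed-amplitude group spec for deterministic single subjects."""
    return GroupSpec(label="HS-like", n_subjects=1, fluct_amplitude=10.0,
                     amplitude_cv=0.0, scanner_noise_sd=5.0, n_frames=200)


def regional_from_rows(rows, tr=3.0):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return RegionalSignalMatrix(signals=rows, tr=tr,
                                region_ids=list(range(1, rows.shape[0] + 1)))


@pytest.fixture
def make_regional():
    return regional_from_rows
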