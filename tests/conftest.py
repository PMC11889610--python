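import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small generated cohort shared by the slower analysis tests."""
    from strokebeta.synthetic import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_subjects=12, seed=42))


@pytest.fixture(scope="session")
def lesion_fixture():
    """Atlas + streamlines + a mid-sized lesion on the synthetic grid."""
    from strokebeta.lesions import VoxelGrid
    from strokebeta.synthetic import make_atlas_fixture, _GRID_SHAPE

    atlas, streams = make_atlas_fixture(rng=7)
    mask = np.zeros(_GRID_SHAPE, dtype=np.uint8)
    mask[13:18, 9:14, 6:13] = 1
    grid = VoxelGrid(mask=mask, voxel_size=(2.0, 2.0, 2.0))
    return atlas, streams, grid
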