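import numpy as np
import pytest

import bsdetect as bs
from bsdetect.bold_io import TimeSeriesMatrix, VoxelSet


def make_matrix(values: np.ndarray, tr: float = 2.0) -> TimeSeriesMatrix:
    """Wrap a bare 2D array in a TimeSeriesMatrix on a synthetic 1D grid."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    indices = np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)], axis=1)
    return TimeSeriesMatrix(
        values=values, voxel_index=VoxelSet(indices=indices, shape=(n, 1, 1)), tr=tr
    )


@pytest.fixture(scope="session")
def default_phantom():
    """One seeded default phantom (burst-suppression present)."""
    cfg = bs.PhantomConfig(seed=11)
    run, truth = bs.simulate_bold(cfg)
    return cfg, run, truth


@pytest.fixture(scope="session")
def detected(default_phantom):
    """Detection result on the default phantom (human preset)."""
    _, run, truth = default_phantom
    return bs.detect_run(run, truth.cortex_mask, species="human")
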