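import numpy as np
import pytest

from fwlomics.core import BinaryMask, ScalarVolume
from fwlomics.cohort import CohortConfig, generate_patient
from fwlomics.regions import build_region_set


@pytest.fixture(scope="session")
def phantom():
    """One deterministic phantom patient on the default 48^3 grid."""
    cfg = CohortConfig(seed=11)
    rng = np.random.default_rng(11)
    return generate_patient(cfg, rng, "P0")


@pytest.fixture(scope="session")
def phantom_regions(phantom):
    return build_region_set(phantom.perfusion, phantom.lung, phantom.gtv, 0.3)


@pytest.fixture()
def tiny_volume():
    """A 4x4x4 ramp volume at 1 mm spacing."""
    vals = np.arange(64, dtype=float).reshape(4, 4, 4)
    return ScalarVolume(vals, (1, 1, 1))


@pytest.fixture()
def ball_mask():
    """Digital ball, radius 10 voxels, at 1 mm spacing."""
    n = 25
    c = (n - 1) / 2
    g = np.indices((n, n, n))
    r2 = sum((a - c) ** 2 for a in g)
    return BinaryMask(r2 <= 10.0**2, (1, 1, 1))
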