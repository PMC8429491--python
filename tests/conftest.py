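import numpy as np
import pytest

from myoregen import generate_synthetic_bundle
from myoregen.geometry import TissueGrid


@pytest.fixture(scope="session")
def bundle():
    """The calibrated 20-fiber bundle used throughout the study."""
    return generate_synthetic_bundle(
        n_fibers=20, target_fibril_count=9864, target_ecm_fraction=0.158, seed=1
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A small 4-fiber bundle for fast simulation tests."""
    return generate_synthetic_bundle(
        n_fibers=4, target_fibril_count=900, target_ecm_fraction=0.2, seed=3
    )


def make_symmetric_four_fiber_grid(block: int = 12, septum: int = 2) -> TissueGrid:
    """Hand-built 2x2 bundle with exact four-fold symmetry (for field tests)."""
    size = 2 * block + 3 * septum
    fiber_id = np.zeros((size, size), dtype=np.int16)
    ecm = np.ones((size, size), dtype=bool)
    for i, (r0, c0) in enumerate(
        [(septum, septum), (septum, block + 2 * septum),
         (block + 2 * septum, septum), (block + 2 * septum, block + 2 * septum)]
    ):
        fiber_id[r0:r0 + block, c0:c0 + block] = i + 1
        ecm[r0:r0 + block, c0:c0 + block] = False
    return TissueGrid(
        fiber_id=fiber_id,
        ecm=ecm,
        occupied=np.ones((size, size), dtype=bool),
        owner=fiber_id.copy(),
        collagen=np.where(ecm, 1.0, 0.0),
        damaged=np.zeros((size, size), dtype=bool),
        needs_repair=np.zeros((size, size), dtype=bool),
        n_fibers=4,
    )
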