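import zlib

import numpy as np
import pytest

from readnet.simulate import (
    BoldSpec, CohortSpec, DEFAULT_NODE_CENTERS, generate_cohort,
)


def scaled_bold_spec(grid=(14, 16, 14), **kwargs) -> BoldSpec:
    """BoldSpec with the default network geometry scaled onto a small grid."""
    scale = np.asarray(grid) * 3.0 / np.asarray((60.0, 72.0, 60.0))
    centers = tuple(
        tuple(np.asarray(c) * scale) for c in DEFAULT_NODE_CENTERS
    )
    kwargs.setdefault("node_radius_mm", max(3.0, 6.0 * scale.min()))
    kwargs.setdefault("n_volumes_per_run", 120)
    kwargs.setdefault("n_runs", 2)
    return BoldSpec(grid_shape=grid, node_centers_mm=centers, **kwargs)


@pytest.fixture(scope="session")
def cohort_1k():
    return generate_cohort(CohortSpec(n_subjects=1000, seed=20))


@pytest.fixture()
def rng(request):
    # deterministic per-test stream, independent of execution order
    seed = zlib.crc32(request.node.name.encode()) % (2 ** 31)
    return np.random.default_rng(seed)
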