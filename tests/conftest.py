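import numpy as np
import pytest

from planconn.cohort import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """Small, fast cohort: 20 nodes (5 per RSN), short scan."""
    return CohortConfig(
        n_subjects=8,
        n_volumes=96,
        network_sizes={"DMN": 5, "FPN": 5, "DAN": 5, "VAN": 5, "other": 0},
        n_low_voxel_nodes=0,
        seed=7,
    )
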