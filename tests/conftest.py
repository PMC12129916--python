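import numpy as np
import pytest

from sinkvec import synth

# printed three-node worked example: a network whose node 3 is the
# strongest sink (largest row norm, largest leading-eigenvector component)
WORKED_A = np.array(
    [
        [0.2, 0.6, 0.0],
        [0.5, 0.3, 0.8],
        [0.0, 0.7, 0.9],
    ]
)
WORKED_LAMBDA = 1.487
WORKED_V1 = np.array([0.287, 0.6155, 0.734])


@pytest.fixture(scope="session")
def worked_matrix():
    return WORKED_A.copy()


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated 8+8 cohort at reduced scale, shared across tests."""
    spec = synth.SyntheticCohortSpec(
        n_success=8, n_failure=8, N=20, fs=500.0, duration_s=20.0, seed=5
    )
    return synth.simulate_cohort(spec)
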