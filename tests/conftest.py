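import numpy as np
import pytest

import netharm as nh


@pytest.fixture(scope="session")
def scheme():
    """Default 45-direction single-shell scheme (b=1200, one b=0)."""
    return nh.make_scheme()


@pytest.fixture(scope="session")
def small_truth():
    """Small planted network for fast generator tests: 20 nodes, 30 core edges."""
    return nh.default_truth(
        n_nodes=20, n_core=30, n_affected=10, spurious_edge_rate=5.0
    )


@pytest.fixture(scope="session")
def default_report():
    """One full default-configuration experiment shared across tests.

    1000 permutations, fixed seed; the acceptance-style properties all read
    from this single run.
    """
    return nh.run_experiment(nh.ExperimentConfig(n_perm=1000, seed=1))
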