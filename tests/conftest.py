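import numpy as np
import pytest

import xwas


@pytest.fixture(scope="session")
def small_panel():
    """200 individuals x 50 SNPs with moderate LD; shared across tests."""
    return xwas.simulate_reference_panel(200, 50, 0.5, (0.1, 0.5), seed=1)


@pytest.fixture(scope="session")
def nold_panel():
    """Independence panel: ld_decay = 0."""
    return xwas.simulate_reference_panel(200, 50, 0.0, (0.1, 0.5), seed=1)


@pytest.fixture(scope="session")
def big_panel():
    """Larger cohort for estimator-accuracy checks."""
    return xwas.simulate_reference_panel(500, 30, 0.3, (0.1, 0.5), seed=7)


def brute_force_xwas_z(W, Z, S):
    """Independent oracle for the gene statistic: explicit loops, no linear
    algebra shared with the implementation."""
    m = len(W)
    num = 0.0
    for i in range(m):
        num += W[i] * Z[i]
    wsw = 0.0
    for i in range(m):
        for j in range(m):
            wsw += W[i] * S[i][j] * W[j]
    return num / wsw**0.5
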