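import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def single_predictor_data(rng):
    """y = 3 x1 + eps with six decoy features and one irrelevant split."""
    n = 60
    X = rng.standard_normal((n, 7))
    y = 3.0 * X[:, 0] + 0.1 * rng.standard_normal(n)
    Z = np.zeros((n, 1))
    Z[rng.permutation(n)[: n // 2], 0] = 1.0
    return X, y, Z
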