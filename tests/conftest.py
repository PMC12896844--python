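import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def randomize_bn2d(bn, rng):
    """Give a BatchNorm2d non-trivial stored statistics and affine params."""
    n = len(bn.running_mean)
    bn.running_mean = rng.normal(0, 0.5, n)
    bn.running_var = rng.uniform(0.5, 2.0, n)
    bn.gamma.data = rng.uniform(0.5, 1.5, n)
    bn.beta.data = rng.normal(0, 0.3, n)


def randomize_bn1d(bn, rng):
    randomize_bn2d(bn, rng)
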