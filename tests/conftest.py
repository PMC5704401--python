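import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles module

from rqaboot import ScalarSeries, gen_noisy_sine


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_series(rng):
    """Gaussian i.i.d. series, length 800."""
    return ScalarSeries(values=rng.normal(size=800), label="iid")


@pytest.fixture
def sine_series():
    """Mildly noisy oscillation, non-integer period so the orbit fills densely."""
    return gen_noisy_sine(1500, period=48.7, amplitude=1.0, noise_sd=0.05, seed=7)
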