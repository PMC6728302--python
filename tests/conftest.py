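import numpy as np
import pytest

from crgof import CRParams, CensoredSample
from crgof.edf import U_EPS, UniformizedSample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_censored_sample(rng, n_max=30, params=None):
    """A random CR censored sample with random (n, r)."""
    params = params or CRParams(
        alpha=float(rng.uniform(0.4, 3.0)), beta=float(rng.uniform(0.2, 4.0))
    )
    n = int(rng.integers(3, n_max + 1))
    r = int(rng.integers(2, n + 1))
    u = rng.random(n)
    x = np.sort(np.sqrt(params.beta * ((1 - u) ** (-1 / params.alpha) - 1)))[:r]
    return CensoredSample(x, n=n), params


def random_uniformized(rng, n_max=25):
    """A random uniformized censored sample (sorted interior uniforms)."""
    n = int(rng.integers(2, n_max + 1))
    r = int(rng.integers(1, n + 1))
    u = np.sort(rng.uniform(U_EPS, 1 - U_EPS, size=n))[:r]
    return UniformizedSample(u=u, n=n)
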