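import numpy as np
import pytest

from spinedgg.params import default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


class ScriptedRng:
    """Deterministic stand-in for the state RNG: returns scripted values
    for normal/uniform draws so rule geometry can be checked exactly."""

    def __init__(self, normals=(), uniforms=()):
        self._normals = list(normals)
        self._uniforms = list(uniforms)

    def normal(self, loc=0.0, scale=1.0, size=None):
        val = self._normals.pop(0) if self._normals else loc
        if size is None:
            return val
        return np.full(size, val)

    def uniform(self, low=0.0, high=1.0):
        if self._uniforms:
            return low + (high - low) * self._uniforms.pop(0)
        return 0.5 * (low + high)

    def exponential(self, scale=1.0):
        return scale


@pytest.fixture()
def scripted_rng():
    return ScriptedRng
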