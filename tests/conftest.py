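import numpy as np
import pytest


class ForcedRng:
    """Generator stand-in that replays a fixed sequence of draw values.

    Each call to uniform/normal pops one value from its queue and fills the
    requested shape with it; integers pops an index.  Lets tests force the
    r1...r7 draws of the update rules to exact values.
    """

    def __init__(self, uniforms=(), normals=(), indices=()):
        self._uniforms = list(uniforms)
        self._normals = list(normals)
        self._indices = list(indices)

    def uniform(self, low=0.0, high=1.0, size=None):
        v = self._uniforms.pop(0)
        if size is None:
            return low + (high - low) * float(v)
        return np.full(size, low + (high - low) * v, dtype=float)

    def normal(self, loc=0.0, scale=1.0, size=None):
        v = self._normals.pop(0)
        if size is None:
            return loc + scale * float(v)
        return np.full(size, loc + scale * v, dtype=float)

    def integers(self, *args, **kwargs):
        return int(self._indices.pop(0))


@pytest.fixture
def forced_rng():
    return ForcedRng


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blobs():
    """Linearly separable 2-class Gaussian blobs: 3 informative + 5 noise."""
    g = np.random.default_rng(7)
    n = 100
    X = g.normal(size=(2 * n, 8))
    y = np.repeat([0, 1], n)
    X[:n, :3] -= 2.5
    X[n:, :3] += 2.5
    return X, y
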