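import numpy as np
import pytest


class PinnedRNG:
    """Stand-in for numpy.random.Generator with every draw pinned.

    Lets tests evaluate update equations by hand: each method returns
    arrays filled with a fixed value.
    """

    def __init__(self, uniform=0.5, normal=0.5, integer=0, t=0.0):
        self.uniform = uniform
        self.normal = normal
        # an int pins every call; a list yields one value per successive call
        self.integer = list(integer) if isinstance(integer, (list, tuple)) else integer
        self.t = t

    @staticmethod
    def _fill(value, size):
        if size is None:
            return value
        return np.full(size, value)

    def random(self, size=None):
        return self._fill(self.uniform, size)

    def standard_normal(self, size=None):
        return self._fill(self.normal, size)

    def integers(self, low, high=None, size=None):
        value = self.integer.pop(0) if isinstance(self.integer, list) else self.integer
        return np.asarray(self._fill(value, size), dtype=int)

    def standard_t(self, df, size=None):
        return self._fill(self.t, size)


@pytest.fixture
def pinned_rng():
    return PinnedRNG


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
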