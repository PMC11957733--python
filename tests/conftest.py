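import numpy as np
import pytest

from tsdax import LabeledWindowSet, separable_fixture


class StubRng:
    """Minimal stand-in for numpy's Generator with scripted draws.

    Any method not scripted falls through to a real seeded generator, so
    tests only pin the draws they care about.
    """

    def __init__(self, *, uniform=None, integers=None, permutation=None, normal=None, choice=None):
        self._uniform = uniform
        self._integers = integers
        self._permutation = permutation
        self._normal = normal
        self._choice = choice
        self._fallback = np.random.default_rng(0)

    def uniform(self, low=0.0, high=1.0, size=None):
        if self._uniform is None:
            return self._fallback.uniform(low, high, size)
        value = self._uniform
        return np.full(size, value) if size is not None else value

    def integers(self, low, high=None, size=None):
        if self._integers is None:
            return self._fallback.integers(low, high, size)
        value = self._integers
        return np.full(size, value, dtype=int) if size is not None else value

    def permutation(self, n):
        if self._permutation is None:
            return self._fallback.permutation(n)
        return np.asarray(self._permutation)

    def normal(self, loc=0.0, scale=1.0, size=None):
        if self._normal is None:
            return self._fallback.normal(loc, scale, size)
        value = self._normal
        return np.full(size, value) if size is not None else value

    def choice(self, a, size=None, replace=True):
        if self._choice is None:
            return self._fallback.choice(a, size=size, replace=replace)
        return self._choice


@pytest.fixture
def stub_rng_factory():
    return StubRng


@pytest.fixture(scope="session")
def fixture_set() -> LabeledWindowSet:
    """Frozen separable two-class window set shared across tests."""
    return separable_fixture(seed=0)


@pytest.fixture
def small_set() -> LabeledWindowSet:
    """Tiny deterministic three-window set (T=8, S=2)."""
    rng = np.random.default_rng(42)
    return LabeledWindowSet(
        data=rng.normal(size=(3, 8, 2)),
        labels=np.array([0, 1, 0]),
        groups=np.array([0, 0, 1]),
    )
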