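import numpy as np
import pytest

from pavaseq import WeightedVector


def random_instance(rng, m_max=50, m_min=1):
    """Weighted vector with repeated values (to exercise constant runs)
    and weights in (0, 2]."""
    m = int(rng.integers(m_min, m_max + 1))
    # half-integer grid values give frequent ties
    values = rng.integers(-4, 5, m) / 2.0
    weights = rng.uniform(0.0, 2.0, m)
    weights[weights == 0.0] = 1.0
    return WeightedVector(values, weights)


def random_increase(rng, data):
    """A random strict single-component increase of ``data``; returns
    (index, new_value)."""
    jo = int(rng.integers(0, data.m))
    bump = float(rng.uniform(0.25, 4.0))
    return jo, float(data.values[jo]) + bump


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
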