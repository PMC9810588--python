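"""Synthetic data for the two benchmark designs, plus small printed fixtures.

Both generators produce families of conditional distributions that increase
in stochastic order with the covariate, which is exactly the assumption the
distributional-regression estimator exploits:

* gamma design: ``X ~ Uniform[0, 10]`` and ``Y | X = x`` gamma with shape
  ``sqrt(x)`` and scale ``2 + (x - 5)/sqrt(2 + (x - 5)^2)``; the scale stays
  inside (1, 3) for every ``x``, and the family is stochastically
  increasing in ``x``;
* Gaussian design: ``(X, Y)`` standard bivariate normal with correlation
  ``rho in [0, 1)``; ``rho`` tunes the strength of the monotone association
  from independence (``rho = 0``) towards a deterministic ordering.

Randomness always flows through an explicit seeded ``numpy`` Generator
(PCG64 via ``default_rng``), so identical seeds give identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .core import WeightedVector

__all__ = [
    "GammaDesign",
    "GaussianDesign",
    "gen_gamma_sample",
    "gen_gauss_sample",
    "gamma_shape",
    "gamma_scale",
    "table_fixture",
]


@dataclass(frozen=True)
class GammaDesign:
    n: int
    seed: int = 0


@dataclass(frozen=True)
class GaussianDesign:
    n: int
    rho: float
    seed: int = 0


def gamma_shape(x):
    """Conditional gamma shape parameter ``sqrt(x)``."""
    return np.sqrt(x)


def gamma_scale(x):
    """Conditional gamma scale ``2 + (x - 5)/sqrt(2 + (x - 5)^2)``, in (1, 3)."""
    x = np.asarray(x, dtype=float)
    return 2.0 + (x - 5.0) / np.sqrt(2.0 + (x - 5.0) ** 2)


def gen_gamma_sample(design: GammaDesign):
    """Draw ``(x, y)`` arrays from the gamma design."""
    if design.n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(design.seed)
    x = rng.uniform(0.0, 10.0, design.n)
    y = rng.gamma(gamma_shape(x), gamma_scale(x))
    return x, y


def gen_gauss_sample(design: GaussianDesign):
    """Draw ``(x, y)`` arrays from the bivariate Gaussian design."""
    if design.n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 <= design.rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(design.seed)
    x = rng.standard_normal(design.n)
    y = design.rho * x + np.sqrt(1.0 - design.rho**2) * rng.standard_normal(
        design.n
    )
    return x, y


# the worked 9-vector example: z, its antitonic fit, and the two
# single-component increases with their fits (all values exact rationals)
_TABLE_Z = [1, 3, 2, 0, -1, 1, Fraction(1, 2), -1, 1]
_TABLE_FIT = [2, 2, 2, Fraction(1, 8), Fraction(1, 8), Fraction(1, 8),
              Fraction(1, 8), 0, 0]
_FIXTURES = {
    "table1": (_TABLE_Z, _TABLE_FIT),
    # component 5 (1-based) raised from -1 to 1
    "table2a": (
        [1, 3, 2, 0, 1, 1, Fraction(1, 2), -1, 1],
        [2, 2, 2, Fraction(2, 3), Fraction(2, 3), Fraction(2, 3),
         Fraction(1, 2), 0, 0],
    ),
    # component 4 (1-based) raised from 0 to 2
    "table2b": (
        [1, 3, 2, 2, -1, 1, Fraction(1, 2), -1, 1],
        [2, 2, 2, 2, Fraction(1, 6), Fraction(1, 6), Fraction(1, 6), 0, 0],
    ),
}


def table_fixture(name: str, exact: bool = False):
    """The printed 9-vector example: ``(WeightedVector, expected fit)``.

    ``name`` is one of ``table1`` (the base vector), ``table2a`` (component
    5 raised from -1 to 1) or ``table2b`` (component 4 raised from 0 to 2).
    With ``exact=True`` the arrays hold ``fractions.Fraction`` entries.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    z, fit = _FIXTURES[name]
    if exact:
        vals = np.array([Fraction(v) for v in z], dtype=object)
        wts = np.array([Fraction(1)] * 9, dtype=object)
        expected = np.array([Fraction(v) for v in fit], dtype=object)
    else:
        vals = np.array([float(v) for v in z])
        wts = np.ones(9)
        expected = np.array([float(v) for v in fit])
    return WeightedVector(vals, wts), expected
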