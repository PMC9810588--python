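"""Isotonic distributional regression under stochastic order.

Given covariate-response pairs ``(X_i, Y_i)`` the goal is to estimate the
whole family of conditional distribution functions ``F_x(y) = P(Y <= y | X
= x)`` under the single assumption that the family increases in stochastic
order: ``F_x(y)`` is non-increasing in ``x`` for every fixed ``y``.

For the unique sorted covariates ``x_1 < ... < x_m`` with multiplicities
``w_j`` the estimator at threshold ``y`` is the weighted antitonic fit of
the per-group empirical CDF vector ``z(y)``, ``z_j(y)`` being the fraction
of responses at ``x_j`` not exceeding ``y``.  As ``y`` sweeps over the
sorted responses, ``z(y)`` changes in exactly one component per
observation, which lets the warm-start (abridged) PAV update recompute each
successive fit in far fewer operations than a from-scratch fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    OpCount,
    SequentialFitter,
    WeightedVector,
    modified_pava,
    standard_pava,
)

__all__ = [
    "AggregatedSample",
    "UpdateSchedule",
    "DistributionalFit",
    "aggregate_sample",
    "ecdf_vector",
    "build_schedule",
    "fit_idr",
    "quantile_curve",
    "cdf_at",
]

VARIANTS = ("standard", "modified", "abridged")


@dataclass(frozen=True)
class AggregatedSample:
    """Sample grouped by covariate: unique sorted ``x``, multiplicities
    ``w`` and, for each group, its (sorted) responses."""

    x: np.ndarray
    w: np.ndarray
    groups: tuple[np.ndarray, ...]

    @property
    def m(self) -> int:
        return self.x.size

    @property
    def n(self) -> int:
        return int(self.w.sum())


@dataclass(frozen=True)
class UpdateSchedule:
    """The response sweep: sorted responses, the covariate-group index each
    one touches, and the per-step increment ``1/w_j`` of that component."""

    thresholds: np.ndarray  # Y_(1) <= ... <= Y_(n)
    touched: np.ndarray  # 0-based group index j_o(t)
    increments: np.ndarray  # 1 / w_{j_o(t)}


@dataclass(frozen=True)
class DistributionalFit:
    """Estimated family of conditional CDFs on the observed grid.

    ``cdf[j, t]`` is the estimate of ``F_{x_j}`` at the t-th unique sorted
    response value.  Columns are antitonic in ``j`` (stochastic ordering),
    rows are nondecreasing in ``t`` with last entry 1 (valid CDFs).
    """

    x: np.ndarray
    thresholds: np.ndarray  # unique sorted response values
    cdf: np.ndarray  # shape (m, T)


def aggregate_sample(x, y) -> AggregatedSample:
    """Group responses by unique covariate value (sorted ascending)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or xa.size < 1 or xa.shape != ya.shape:
        raise ValueError("x and y must be equal-length non-empty 1-d arrays")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("x and y must be finite")
    ux, inv, counts = np.unique(xa, return_inverse=True, return_counts=True)
    order = np.lexsort((ya, inv))
    groups = tuple(
        np.array(g) for g in np.split(ya[order], np.cumsum(counts)[:-1])
    )
    return AggregatedSample(ux, counts.astype(np.int64), groups)


def ecdf_vector(agg: AggregatedSample, y: float) -> WeightedVector:
    """The vector ``z(y)``: per-group fraction of responses ``<= y``."""
    z = np.array(
        [np.searchsorted(g, y, side="right") / w
         for g, w in zip(agg.groups, agg.w.tolist())]
    )
    return WeightedVector(z, agg.w.astype(float))


def build_schedule(agg: AggregatedSample) -> UpdateSchedule:
    """Single-component increments reproducing ``z(y)`` at each threshold."""
    pairs = [(float(yv), j) for j, g in enumerate(agg.groups) for yv in g]
    pairs.sort()
    thr = np.array([p[0] for p in pairs])
    touched = np.array([p[1] for p in pairs], dtype=np.int64)
    increments = 1.0 / agg.w[touched]
    return UpdateSchedule(thr, touched, increments)


def _sweep_scratch(agg: AggregatedSample, variant: str):
    """Fit A(z(y)) independently at every unique threshold."""
    fit = standard_pava if variant == "standard" else modified_pava
    thr = np.unique(np.concatenate([g for g in agg.groups]))
    m = agg.m
    cdf = np.empty((m, thr.size))
    ops = OpCount()
    w = agg.w.astype(float)
    # per-group counts of responses <= y, vectorized over the grid
    counts = np.vstack(
        [np.searchsorted(g, thr, side="right") for g in agg.groups]
    ).astype(float)
    zmat = counts / w[:, None]
    for t in range(thr.size):
        res = fit(WeightedVector(zmat[:, t], w))
        cdf[:, t] = res.fitted
        ops = ops + res.ops
    return DistributionalFit(agg.x, thr, cdf), ops


def _sweep_abridged(agg: AggregatedSample):
    """Sweep the sorted responses once, warm-starting every fit."""
    sched = build_schedule(agg)
    m = agg.m
    n = sched.thresholds.size
    fitter = SequentialFitter(
        WeightedVector(np.zeros(m), agg.w.astype(float))
    )
    thr_unique = np.unique(sched.thresholds)
    cdf = np.empty((m, thr_unique.size))
    col = 0
    counts = np.zeros(m, dtype=np.int64)
    w = agg.w
    for t in range(n):
        jo = int(sched.touched[t])
        # new component value as an exact ratio count/weight, so that the
        # sweep reproduces z(y) bit-for-bit and ends at the all-ones vector
        counts[jo] += 1
        fitter.increase(jo, counts[jo] / w[jo])
        # emit a column only once all tied responses are absorbed
        if t + 1 == n or sched.thresholds[t + 1] > sched.thresholds[t]:
            cdf[:, col] = fitter.fitted()
            col += 1
    return DistributionalFit(agg.x, thr_unique, cdf), fitter.ops


def fit_idr(x, y, variant: str = "abridged"):
    """Estimate the conditional-CDF family; returns ``(fit, op_count)``.

    All three variants produce the same matrix; they differ only in how
    each per-threshold antitonic fit is obtained (and hence in the number
    of averaging operations performed).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    agg = aggregate_sample(x, y)
    if variant == "abridged":
        return _sweep_abridged(agg)
    return _sweep_scratch(agg, variant)


def quantile_curve(fit: DistributionalFit, beta: float) -> np.ndarray:
    """Per-covariate generalized-inverse quantile
    ``q_beta(x_j) = min{y : F_hat_{x_j}(y) >= beta}``.

    Nondecreasing in ``j`` for fixed ``beta`` (stochastic order).
    """
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    # rows are nondecreasing; pad tolerance-free since the last entry is 1
    idx = np.apply_along_axis(
        lambda row: np.searchsorted(row, beta, side="left"), 1, fit.cdf
    )
    idx = np.minimum(idx, fit.thresholds.size - 1)
    return fit.thresholds[idx]


def cdf_at(fit: DistributionalFit, j: int, y: float) -> float:
    """Right-continuous step evaluation of ``F_hat_{x_j}`` at ``y``."""
    if not 0 <= j < fit.x.size:
        raise IndexError(f"covariate index {j} out of range")
    t = np.searchsorted(fit.thresholds, y, side="right") - 1
    if t < 0:
        return 0.0
    return float(fit.cdf[j, t])
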