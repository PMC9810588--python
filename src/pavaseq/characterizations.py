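"""Independent characterizations of the antitonic least-squares fit.

Two classical characterizations of ``A(z)`` are implemented directly from
their definitions, deliberately by brute force, so that they can serve as
trustworthy ground truth for the PAV algorithms:

* the *min-max formula*: ``A_j(z)`` is the min over lower endpoints
  ``a <= j`` of the max over upper endpoints ``b >= j`` of the weighted mean
  of ``z`` over ``{a..b}`` (under a total order, upper sets are suffixes and
  lower sets are prefixes, so every intersection is an interval);
* the *level-set optimality conditions*: an antitonic ``f`` equals ``A(z)``
  iff on every level set (a contiguous block under the total order) all
  suffix means of ``z`` are >= the level and all prefix means are <= the
  level — in particular each level equals the block mean of ``z``.

A third routine checks the qualitative behaviour of the fit under
componentwise increases of ``z`` (monotonicity of the fit, invariance of the
strictly smaller / strictly larger level sets, and merging-only behaviour of
the level sets left of the change), which underpins the warm-start update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import WeightedVector

__all__ = [
    "minmax_fit",
    "verify_char2",
    "check_update_properties",
    "Violation",
]

#: |slack| below this counts as satisfied for float inputs; exact (object
#: dtype, e.g. Fraction) inputs are checked with zero tolerance.
FLOAT_TOL = 1e-10


def minmax_fit(data: WeightedVector) -> np.ndarray:
    """Antitonic fit via the min-max formula (O(m^2) floats, O(m^3) exact).

    Intended as an oracle on small inputs.  With ``fractions.Fraction``
    entries the computation is exact.
    """
    m = data.m
    if data.values.dtype == object:
        vals = data.values.tolist()
        wts = data.weights.tolist()
        out = np.empty(m, dtype=object)
        for j in range(m):
            best = None
            for a in range(j + 1):
                # max over b >= j of the mean on {a..b}
                sw = sum(wts[a : j + 1], start=0)
                sz = sum((w * v for w, v in zip(wts[a : j + 1], vals[a : j + 1])),
                         start=0)
                cur = sz / sw
                for b in range(j + 1, m):
                    sw += wts[b]
                    sz += wts[b] * vals[b]
                    mu = sz / sw
                    if mu > cur:
                        cur = mu
                if best is None or cur < best:
                    best = cur
            out[j] = best
        return out
    w = np.asarray(data.weights, float)
    wz = w * np.asarray(data.values, float)
    cw = np.concatenate(([0.0], np.cumsum(w)))
    cz = np.concatenate(([0.0], np.cumsum(wz)))
    # interval means E[a, b] over {a..b}, 0-based inclusive
    denom = cw[None, 1:] - cw[:-1, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = (cz[None, 1:] - cz[:-1, None]) / denom
    means = np.where(denom > 0, means, -np.inf)
    # G[a, j] = max_{b >= j} E[a, b]; A_j = min_{a <= j} G[a, j]
    suffix_max = np.maximum.accumulate(means[:, ::-1], axis=1)[:, ::-1]
    suffix_max = np.where(denom > 0, suffix_max, np.inf)
    return np.minimum.accumulate(suffix_max, axis=0).diagonal().copy()


def maxmin_fit(data: WeightedVector) -> np.ndarray:
    """The dual max-min form of the formula; agrees with :func:`minmax_fit`."""
    flipped = WeightedVector(
        np.array([-v for v in data.values.tolist()],
                 dtype=data.values.dtype if data.values.dtype == object else float)[::-1],
        np.array(data.weights)[::-1],
    )
    return -minmax_fit(flipped)[::-1]


@dataclass(frozen=True)
class Violation:
    """One violated optimality condition, with its witness interval."""

    level: float
    lo: int  # 0-based inclusive
    hi: int  # 0-based inclusive
    direction: str  # 'upper-mean-too-small' | 'lower-mean-too-large' | 'level-not-block-mean'
    slack: float


def _is_antitonic(f, tol) -> bool:
    return all(a >= b - tol for a, b in zip(f, f[1:]))


def verify_char2(data: WeightedVector, candidate) -> list[Violation]:
    """Check the level-set optimality conditions of a candidate fit.

    Returns an empty list iff ``candidate`` equals ``A(z)``.  For each block
    ``{p..q}`` on which the candidate is constant at level ``xi``: every
    suffix ``{i..q}`` must have weighted ``z``-mean >= ``xi`` and every
    prefix ``{p..i}`` mean <= ``xi``; the full block mean must equal ``xi``.
    """
    f = np.asarray(candidate).tolist() if not isinstance(candidate, np.ndarray) \
        else candidate.tolist()
    vals = data.values.tolist()
    wts = data.weights.tolist()
    m = data.m
    if len(f) != m:
        raise ValueError("candidate length does not match the data")
    exact = data.values.dtype == object
    tol = 0 if exact else FLOAT_TOL
    if not _is_antitonic(f, tol):
        raise ValueError("candidate is not antitonic")
    report: list[Violation] = []
    p = 0
    while p < m:
        q = p
        while q + 1 < m and f[q + 1] == f[p]:
            q += 1
        xi = f[p]
        # suffix means {i..q} must be >= xi (suffixes of the block are the
        # intersections of the block with upper sets)
        sw = 0
        sz = 0
        for i in range(q, p - 1, -1):
            sw += wts[i]
            sz += wts[i] * vals[i]
            mu = sz / sw
            if mu < xi - tol:
                report.append(Violation(float(xi), i, q,
                                        "upper-mean-too-small",
                                        float(mu - xi)))
        # prefix means {p..i} must be <= xi
        sw = 0
        sz = 0
        for i in range(p, q + 1):
            sw += wts[i]
            sz += wts[i] * vals[i]
            mu = sz / sw
            if mu > xi + tol:
                report.append(Violation(float(xi), p, i,
                                        "lower-mean-too-large",
                                        float(mu - xi)))
        block_mean = sz / sw
        if abs(block_mean - xi) > tol:
            report.append(Violation(float(xi), p, q,
                                    "level-not-block-mean",
                                    float(block_mean - xi)))
        p = q + 1
    return report


def check_update_properties(
    z: WeightedVector, z_new: WeightedVector, fit, fit_new, tol: float = 1e-9
) -> dict[str, tuple[bool, object]]:
    """Check how the fit responds to a componentwise increase of ``z``.

    ``fit``/``fit_new`` must be the antitonic solutions for ``z``/``z_new``
    with ``z_new >= z`` componentwise.  Returns a mapping from property name
    to ``(passed, witness)`` where the witness is ``None`` on success and an
    offending index (pair) otherwise:

    - ``monotone``: the fit increases componentwise;
    - ``low-level-sets-fixed``: components with old fitted value strictly
      below the smallest old fitted value on the changed set are unchanged;
    - ``high-level-sets-fixed``: components with new fitted value strictly
      above the largest new fitted value on the changed set are unchanged;
    - ``ties-preserved-left``: indices tied in the old fit and lying at or
      left of every changed index remain tied;
    - ``right-part-fixed`` (changed set left of a strict descent): the fit
      right of the descent is unchanged;
    - ``left-part-fixed`` (changed set right of a strict new-fit descent):
      the fit left of the descent is unchanged;
    - ``descents-coarsen-left``: left of the changed set, strict descents of
      the new fit occur only where the old fit had them.
    """
    f = np.asarray(fit, dtype=float)
    g = np.asarray(fit_new, dtype=float)
    zv = np.asarray(z.values, dtype=float)
    zt = np.asarray(z_new.values, dtype=float)
    if np.any(zt < zv - 1e-15):
        raise ValueError("z_new must dominate z componentwise")
    m = z.m
    K = np.flatnonzero(zt > zv)
    out: dict[str, tuple[bool, object]] = {}

    def record(name, mask_bad):
        bad = np.flatnonzero(mask_bad)
        out[name] = (bad.size == 0, int(bad[0]) if bad.size else None)

    record("monotone", g < f - tol)
    if K.size == 0:
        # no strict change: the fit must be identical
        record("unchanged", np.abs(g - f) > tol)
        return out

    min_fK = f[K].min()
    record("low-level-sets-fixed",
           (f < min_fK - tol) & (np.abs(g - f) > tol))
    max_gK = g[K].max()
    record("high-level-sets-fixed",
           (g > max_gK + tol) & (np.abs(g - f) > tol))

    kmin = K.min()
    tie_bad = None
    for i in range(kmin):
        if abs(f[i] - f[kmin]) <= tol and abs(g[i] - g[kmin]) > tol:
            tie_bad = i
            break
    # ties among {i, j} <= every changed index must persist in the new fit
    left = slice(0, kmin + 1)
    fl, gl = f[left], g[left]
    ok = True
    wit = tie_bad
    if wit is None:
        for i in range(len(fl)):
            for j in range(i + 1, len(fl)):
                if abs(fl[i] - fl[j]) <= tol and abs(gl[i] - gl[j]) > tol:
                    ok, wit = False, (i, j)
                    break
            if not ok:
                break
    else:
        ok = False
    out["ties-preserved-left"] = (ok, wit)

    kmax = K.max()
    # changed set entirely weakly left of a strict old-fit descent at k
    for k in range(kmax, m - 1):
        if f[k] > f[k + 1] + tol:
            record("right-part-fixed", np.abs(g[k + 1 :] - f[k + 1 :]) > tol)
            break
    # changed set entirely right of a strict new-fit descent at k-1 -> k
    for k in range(kmin, 0, -1):
        if g[k - 1] > g[k] + tol:
            record("left-part-fixed", np.abs(g[:k] - f[:k]) > tol)
            break
    # descents of g strictly left of kmin are a subset of descents of f
    desc_f = f[:-1] > f[1:] + tol
    desc_g = g[:-1] > g[1:] + tol
    idx = np.arange(m - 1) < kmin
    record("descents-coarsen-left", idx & desc_g & ~desc_f)
    return out
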