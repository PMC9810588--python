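# Methods

## Model and estimator

The core primitive is weighted least-squares projection onto the antitonic
cone `ℝ^m_↓ = {f : f_1 ≥ … ≥ f_m}` under a total order of the covariates.
The projection `A(z)` exists and is unique (strictly convex objective,
closed convex cone) and is characterized two ways, both implemented in
`characterizations.py` as test-time ground truth:

* **min-max formula** — `A_j(z) = min_{a ≤ j} max_{b ≥ j} M_{a..b}(z)`
  where `M_{a..b}` is the weighted mean over the interval `{a..b}`; under a
  total order upper sets are suffixes and lower sets are prefixes, so only
  intervals occur. The dual max-min form is also implemented and tested to
  agree.
* **level-set optimality** — an antitonic `f` equals `A(z)` iff on every
  constancy block every suffix mean of `z` is ≥ the level and every prefix
  mean is ≤ the level; in particular every level equals its block's
  weighted mean.

Isotonic distributional regression estimates the family of conditional
CDFs `F_x` under the single shape constraint of stochastic ordering
(`F_{x}(y)` non-increasing in `x` for each `y`). For each response
threshold `y`, the estimate is the antitonic fit of the per-group empirical
CDF vector `z(y)`. The resulting matrix automatically has antitonic
columns (stochastic order across covariates) and nondecreasing rows with
last column 1 (valid CDFs — rows grow because raising a component of `z`
can only raise the fit).

## Algorithms

All three PAV variants share one dtype-agnostic engine (`core.py`) that
works on plain Python lists of block boundaries, weights and means, so the
identical code path runs in float64 or in exact `fractions.Fraction`
arithmetic. Pooling uses the literal predicate `M_{d−1} ≤ M_d` with no
numerical tolerance; equal adjacent means are merged, which guarantees
strictly decreasing final block means. Borderline float cases are
adjudicated in tests by re-running the same engine on exact rationals.

* **standard** seeds one singleton block per index;
* **modified** seeds one block per maximal constant run of `z` (pooling an
  already-constant run up front is always valid); with empirical-CDF input
  vectors, which are step functions, this removes most of the work;
* **abridged** (warm start) handles a strict single-component increase at
  index `j_o`: blocks strictly left of the block `P_{s_o}` containing
  `j_o` are reused, the partial block up to `j_o` is re-seeded with the new
  mean and pooled backwards, the remainder of `P_{s_o}` re-enters one index
  at a time, and all blocks right of `P_{s_o}` are appended verbatim.
  Decreases and multi-component changes are rejected with an error rather
  than silently degraded; callers re-fit with `modified_pava` instead. The
  update never mutates the previous state. `SequentialFitter` wraps the
  same engine mutably for long update chains.

Block means are always combined pairwise, `(W₁M₁ + W₂M₂)/(W₁ + W₂)`, never
recomputed from scratch, so operation counts reflect the averaging-
operation model below.

## Operation-count model

`OpCount` counts *averaging operations*: `pool_merges` is the number of
pairwise pooling combinations; `block_inits` counts the block-seeding mean
computations each variant performs — one per index for standard, one per
maximal constant run for modified, and exactly one per abridged update
(the re-seeded partial block). Singleton blocks that re-enter during the
abridged induction step are not counted as seeds: their "mean" is a stored
component value and involves no averaging. Under this model the abridged
update satisfies the bound `total ≤ d + |P_{s_o}|` (previous block count
plus touched-block size) with worst case exactly `m`, attained by the
strictly decreasing staircase `z_i = m − i` when its last component is
raised above everything. Counting induction singletons as seeds would
break that bound (e.g. `z = (0,1,1,1)`, `j_o = 1` raised far above: four
seeds plus two merges exceed the bound of five), which is why the model
distinguishes them. Note the bound itself can exceed `m` in degenerate
cases (`m = 1` gives `d + |P| = 2`) while the count never does; tests
assert both inequalities separately.

## Distributional sweep

`fit_idr` aggregates the sample (`numpy.unique` + one lexsort), then either
fits every threshold from scratch (standard/modified variants, used as the
reference route) or sweeps the sorted responses once with the warm-start
update. During the sweep each component is set to the exact ratio
`count/weight` rather than accumulated by increments, so all variants see
bit-identical `z(y)` vectors and the final column is exactly 1. Tied
response values are absorbed one observation at a time — each is a valid
strict single-component increase — and only the state after the last tied
observation is emitted as that threshold's column, since the estimator is
defined per distinct threshold. Quantiles use the left-continuous
generalized inverse `q_β(x_j) = min{y : F̂_{x_j}(y) ≥ β}`; CDF evaluation
between thresholds is the right-continuous step interpolation. Predictions
are exposed only at observed covariates: the estimator is defined on
`x_1 … x_m`, and any between-covariate interpolation would be a
presentation choice, not a statistical claim. Dense `m × T` storage is
used; it is the simplest representation at the desk scales (n up to ~10⁴)
the package targets.

## Synthetic designs

Both generators draw from an explicit `numpy.random.default_rng(seed)`
(PCG64), with no global state, so fixed seeds reproduce samples exactly.

* **Gamma design** — `X ~ Uniform[0, 10]`, `Y | X = x` gamma with shape
  `√x` and scale `2 + (x − 5)/√(2 + (x − 5)²)`. The scale lies in (1, 3)
  for every `x` and the family is stochastically increasing in `x`, so the
  shape constraint of the estimator holds in truth. Continuous covariates
  make all group weights 1 almost surely; generators never deduplicate —
  aggregation is the estimator's job.
* **Gaussian design** — standard bivariate normal with correlation
  `ρ ∈ [0, 1)`, generated as `Y = ρX + √(1−ρ²)ε`. `ρ` tunes the strength
  of the monotone association from independence to near-deterministic
  ordering; operation counts are invariant under strictly increasing
  transformations of either margin, so the standard-margins choice is
  without loss of generality.

What the generators do *not* emulate: heteroscedastic families beyond the
two laws above, discrete or heavily tied covariates (ties do occur in the
tests via integer-valued designs, not via these generators), model
misspecification (non-monotone families), and outliers. Passing tests
therefore demonstrate algorithmic correctness and the qualitative
efficiency claims, not robustness of IDR on arbitrary real data.

## Benchmarking

`bench.run_benchmark` fits every replication's sample with all three
variants (identical data per replication; replication seeds are spawned
from a single `SeedSequence`) and records exact operation totals; ratios
are summarized across replications. Wall time is recorded only behind an
explicit flag and labelled informational — absolute timings depend on
hardware and interpreter and are deliberately not comparison targets. The
validated claims are orderings (abridged ≤ modified ≤ standard on every
replication) and the monotone growth of the standard/abridged ratio with
`ρ`: weak association concentrates the partition into few, large middle
blocks whose re-seeding is expensive, while strong association keeps the
touched blocks small.

## Problem sizes and numerical choices

The test and acceptance suites use m ≤ 50 for the thousand-instance
oracle-equivalence sweep (with exact-rational spot checks at m ≤ 12),
n ∈ {200, 1000} for the distributional-regression equivalence checks and
n = 1000 with 20 replications per correlation for the ratio trend —
sizes at which the brute-force oracle remains a meaningful independent
check while the full suite stays fast. The float verifier treats
|slack| ≤ 1e−10 as satisfied; exact mode uses zero tolerance. Cross-route
comparisons in float use 1e−12 absolute tolerance, which covers
combination-order rounding differences between variants. Degenerate inputs
(m = 1, all-equal vectors) are ordinary single-block fits; empty inputs
and non-positive weights are rejected.

## Known limitations

* Only total orders: general partial orders (and recursive-partitioning
  approaches to them) are out of scope.
* Only single-component *increases* are warm-started; a symmetric decrease
  variant is not provided.
* The increasing (isotonic) convention is exposed only as a sign-flip
  helper, and only squared-error loss is supported.
* No scoring rules (e.g. CRPS), density estimation, or covariate
  interpolation for the distributional fit.
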