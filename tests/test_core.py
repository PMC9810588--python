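"""Unit tests for the block-partition state machine and the PAV variants."""

from fractions import Fraction

import numpy as np
import pytest

from pavaseq import (
    Delta,
    FitState,
    OpCount,
    SequentialFitter,
    WeightedVector,
    abridged_update,
    expand_fit,
    isotonic_fit,
    modified_pava,
    pool_violators,
    standard_pava,
)
from pavaseq.core import _abridged_inplace
from pavaseq.simulate import table_fixture

from conftest import random_increase, random_instance


class TestStandardPava:
    @pytest.mark.parametrize(
        "z, w, expected, d",
        [
            # the printed 9-vector worked example
            ([1, 3, 2, 0, -1, 1, 0.5, -1, 1], None,
             [2, 2, 2, 0.125, 0.125, 0.125, 0.125, 0, 0], 3),
            # already antitonic: the fit is the data itself
            ([3, 2, 1], [2.0, 0.5, 1.0], [3, 2, 1], 3),
            # full pooling forced; weighted mean (0*1 + 1*3)/4
            ([0, 1], [1, 3], [0.75, 0.75], 1),
            ([7], [2], [7], 1),
        ],
    )
    def test_examples(self, z, w, expected, d):
        res = standard_pava(WeightedVector(z, w))
        np.testing.assert_allclose(res.fitted, expected, rtol=0, atol=1e-15)
        assert res.state.d == d

    def test_block_means_strictly_decreasing(self, rng):
        for _ in range(100):
            res = standard_pava(random_instance(rng))
            means = res.state.block_means
            assert np.all(np.diff(means) < 0)

    def test_state_consistency(self, rng):
        data = random_instance(rng, m_max=20)
        res = standard_pava(data)
        b = res.state.boundaries
        for s in range(res.state.d):
            sl = slice(b[s], b[s + 1])
            w = data.weights[sl]
            assert np.isclose(res.state.block_weights[s], w.sum())
            assert np.isclose(
                res.state.block_means[s], np.average(data.values[sl], weights=w)
            )

    def test_idempotence(self, rng):
        for _ in range(50):
            data = random_instance(rng)
            fit1 = standard_pava(data).fitted
            fit2 = standard_pava(WeightedVector(fit1, data.weights)).fitted
            np.testing.assert_allclose(fit2, fit1, atol=1e-12)

    def test_mean_conservation(self, rng):
        for _ in range(50):
            data = random_instance(rng)
            fit = standard_pava(data).fitted
            assert np.isclose(
                np.average(fit, weights=data.weights),
                np.average(data.values, weights=data.weights),
                atol=1e-12,
            )

    def test_exact_rational_input(self):
        data, expected = table_fixture("table1", exact=True)
        res = standard_pava(data)
        assert list(res.fitted) == list(expected)
        assert all(isinstance(v, Fraction) for v in res.fitted)


class TestModifiedPava:
    def test_runs_seeded_as_blocks(self):
        res = modified_pava(WeightedVector([1, 1, 1, 0, 0]))
        np.testing.assert_array_equal(res.fitted, [1, 1, 1, 0, 0])
        assert res.ops.block_inits == 2
        assert res.ops.pool_merges == 0

    def test_runs_pooled_to_global_mean(self):
        res = modified_pava(WeightedVector([0, 0, 1, 1]))
        np.testing.assert_allclose(res.fitted, [0.5] * 4)
        assert res.ops.block_inits == 2

    def test_agrees_with_standard(self, rng):
        data, expected = table_fixture("table1")
        np.testing.assert_array_equal(modified_pava(data).fitted, expected)
        for _ in range(100):
            data = random_instance(rng)
            np.testing.assert_allclose(
                modified_pava(data).fitted, standard_pava(data).fitted,
                atol=1e-12,
            )

    def test_never_more_ops_than_standard(self, rng):
        for _ in range(100):
            data = random_instance(rng)
            assert modified_pava(data).ops.total <= standard_pava(data).ops.total


class TestAbridgedUpdate:
    def test_table2_first_update(self):
        data, _ = table_fixture("table1")
        prev = standard_pava(data)
        res = abridged_update(prev.state, data, Delta(4, 1.0))
        _, expected = table_fixture("table2a")
        np.testing.assert_allclose(res.fitted, expected, atol=1e-15)
        assert res.state.d == 4
        # indices beyond the touched block (0-based 7, 8) are copied verbatim
        np.testing.assert_array_equal(res.fitted[7:], prev.fitted[7:])

    def test_table2_second_update(self):
        data, _ = table_fixture("table1")
        prev = standard_pava(data)
        res = abridged_update(prev.state, data, Delta(3, 2.0))
        _, expected = table_fixture("table2b")
        np.testing.assert_allclose(res.fitted, expected, atol=1e-15)
        assert res.state.d == 3

    def test_worst_case_touches_everything(self):
        m = 8
        data = WeightedVector(np.arange(m - 1, -1.0, -1))
        prev = standard_pava(data)
        res = abridged_update(prev.state, data, Delta(m - 1, float(m * m)))
        expected = np.full(m, (np.arange(1.0, m) .sum() + m * m) / m)
        np.testing.assert_allclose(res.fitted, expected)
        assert res.state.d == 1  # the cascade reached index 0
        assert res.ops.total == m  # exactly m averaging operations

    def test_matches_standard_on_random_increases(self, rng):
        for _ in range(200):
            data = random_instance(rng)
            prev = standard_pava(data)
            jo, new = random_increase(rng, data)
            res = abridged_update(prev.state, data, Delta(jo, new))
            ref = standard_pava(data.replace(jo, new))
            np.testing.assert_allclose(res.fitted, ref.fitted, atol=1e-12)

    def test_operation_bound(self, rng):
        for _ in range(200):
            data = random_instance(rng)
            prev = standard_pava(data)
            jo, new = random_increase(rng, data)
            res = abridged_update(prev.state, data, Delta(jo, new))
            s = prev.state.block_of(jo)
            b = prev.state.boundaries
            assert res.ops.total <= prev.state.d + (b[s + 1] - b[s])
            assert res.ops.total <= data.m

    def test_rejects_decrease_and_noop(self):
        data, _ = table_fixture("table1")
        prev = standard_pava(data)
        with pytest.raises(ValueError, match="strict single-component"):
            abridged_update(prev.state, data, Delta(4, -2.0))
        with pytest.raises(ValueError, match="strict single-component"):
            abridged_update(prev.state, data, Delta(4, -1.0))
        with pytest.raises(IndexError):
            abridged_update(prev.state, data, Delta(9, 5.0))

    def test_rejects_partial_state(self):
        data, _ = table_fixture("table1")
        partial = FitState([0, 3], [3.0], [2.0])
        with pytest.raises(ValueError, match="cover"):
            abridged_update(partial, data, Delta(4, 1.0))

    def test_prev_state_not_mutated(self):
        data, _ = table_fixture("table1")
        prev = standard_pava(data)
        snap = (prev.state.boundaries.copy(), prev.state.block_means.copy())
        abridged_update(prev.state, data, Delta(4, 1.0))
        np.testing.assert_array_equal(prev.state.boundaries, snap[0])
        np.testing.assert_array_equal(prev.state.block_means, snap[1])

    def test_engine_reads_only_touched_block(self):
        """The warm-start engine must not inspect components outside the
        block containing the changed index."""

        class Guard(list):
            def __init__(self, data, lo, hi):
                super().__init__(data)
                self.lo, self.hi = lo, hi

            def __getitem__(self, i):
                assert self.lo <= i < self.hi, f"read outside [{self.lo},{self.hi})"
                return super().__getitem__(i)

        data, _ = table_fixture("table1")
        prev = standard_pava(data)
        # raise 0-based component 4; its block is [3, 7)
        values = data.values.tolist()
        values[4] = 1.0
        ends = prev.state.boundaries[1:].tolist()
        W = prev.state.block_weights.tolist()
        M = prev.state.block_means.tolist()
        _abridged_inplace(
            ends, W, M, Guard(values, 3, 7), Guard(data.weights.tolist(), 3, 7),
            4, OpCount(),
        )
        fitted = np.repeat(M, np.diff([0] + ends))
        _, expected = table_fixture("table2a")
        np.testing.assert_allclose(fitted, expected)


class TestPoolViolators:
    def test_single_trailing_merge(self):
        state = FitState([0, 3, 4, 5], [3, 1, 1], [2.0, 0.0, 1.0])
        out = pool_violators(state)
        np.testing.assert_allclose(out.block_means, [2.0, 0.5])
        np.testing.assert_allclose(out.block_weights, [3.0, 2.0])

    def test_noop_when_decreasing(self):
        state = FitState([0, 1, 2, 3], [1, 1, 1], [3.0, 2.0, 1.0])
        out = pool_violators(state)
        np.testing.assert_array_equal(out.block_means, state.block_means)

    def test_equality_triggers_pooling(self):
        ops = OpCount()
        out = pool_violators(FitState([0, 1, 2], [1, 1], [0.0, 0.0]), ops)
        assert out.d == 1
        assert out.block_means[0] == 0.0
        assert ops.pool_merges == 1


class TestExpandFit:
    def test_table_row(self):
        state = FitState([0, 3, 7, 9], [3, 4, 2], [2.0, 0.125, 0.0])
        np.testing.assert_array_equal(
            expand_fit(state), [2, 2, 2, 0.125, 0.125, 0.125, 0.125, 0, 0]
        )

    def test_degenerate(self):
        np.testing.assert_array_equal(
            expand_fit(FitState([0, 5], [5.0], [3.0])), [3.0] * 5
        )
        np.testing.assert_array_equal(
            expand_fit(FitState([0, 1], [1.0], [7.0])), [7.0]
        )

    def test_unfinalized_state_rejected(self):
        with pytest.raises(ValueError, match="covers"):
            expand_fit(FitState([0, 3], [3.0], [2.0]), m=9)


class TestValidation:
    def test_empty_input(self):
        with pytest.raises(ValueError):
            WeightedVector([])

    def test_nonpositive_weight(self):
        with pytest.raises(ValueError, match="positive"):
            WeightedVector([1, 2], [1, 0])
        with pytest.raises(ValueError, match="positive"):
            WeightedVector([1, 2], [1, -1])

    def test_nonfinite(self):
        with pytest.raises(ValueError):
            WeightedVector([1, np.nan])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            WeightedVector([1, 2, 3], [1, 1])


def test_agrees_with_sklearn_isotonic(rng):
    """Cross-check against an established independent implementation."""
    from sklearn.isotonic import isotonic_regression

    for _ in range(50):
        data = random_instance(rng, m_max=40)
        ref = isotonic_regression(
            np.asarray(data.values, float),
            sample_weight=np.asarray(data.weights, float),
            increasing=False,
        )
        np.testing.assert_allclose(standard_pava(data).fitted, ref, atol=1e-9)


def test_isotonic_helper_is_sign_flip():
    data = WeightedVector([1, 0, 2, 5, 4], np.ones(5))
    inc = isotonic_fit(data)
    assert np.all(np.diff(inc) >= 0)
    dec = standard_pava(WeightedVector(-data.values, data.weights)).fitted
    np.testing.assert_allclose(inc, -dec)


def test_sequential_fitter_matches_functional_updates(rng):
    data = random_instance(rng, m_max=30)
    fitter = SequentialFitter(data)
    state, cur = standard_pava(data).state, data
    for _ in range(20):
        jo, new = random_increase(rng, cur)
        fitter.increase(jo, new)
        res = abridged_update(state, cur, Delta(jo, new))
        state, cur = res.state, cur.replace(jo, new)
        np.testing.assert_allclose(fitter.fitted(), res.fitted, atol=1e-12)
    assert fitter.state().d == state.d
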