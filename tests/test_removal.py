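"""Removal-scheme unit and oracle tests.

The brute-force reference implementation below is intentionally naive
(python loops over an explicit matrix copy) and is kept independent of the
package's vectorized path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stackprune.removal import (
    CorrelationMatrix,
    RemovalConfig,
    find_max_pair,
    prediction_correlation_matrix,
    removal_iteration,
    run_removal,
    run_removal_matrix,
)


def brute_force_survivors(names, matrix, threshold, cv_aucs=None):
    """Naive reference: repeatedly scan, drop, and rebuild."""
    names = list(names)
    matrix = [row[:] for row in np.asarray(matrix).tolist()]
    cv_aucs = cv_aucs or {}
    while len(names) > 1:
        best_val = -2.0
        best_pair = None
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pair = tuple(sorted((names[i], names[j])))
                if matrix[i][j] > best_val + 1e-12 or (
                    abs(matrix[i][j] - best_val) <= 1e-12
                    and (best_pair is None or pair < best_pair)
                ):
                    best_val = max(best_val, matrix[i][j])
                    best_pair = pair
        if best_val <= threshold:
            break
        a, b = best_pair
        ia, ib = names.index(a), names.index(b)
        avg_a = sum(matrix[ia][k] for k in range(len(names)) if k != ia) / (len(names) - 1)
        avg_b = sum(matrix[ib][k] for k in range(len(names)) if k != ib) / (len(names) - 1)
        if avg_a > avg_b:
            drop = ia
        elif avg_b > avg_a:
            drop = ib
        else:
            drop = ia if cv_aucs.get(a, 0.0) <= cv_aucs.get(b, 0.0) else ib
        del names[drop]
        matrix = [
            [v for k, v in enumerate(row) if k != drop]
            for k, row in enumerate(matrix)
            if k != drop
        ]
    return names


def _corr(names, values):
    return CorrelationMatrix(learner_names=tuple(names), values=np.asarray(values, float))


def random_corr_matrix(l, rng):
    """Random symmetric unit-diagonal matrix on a 0.05 grid."""
    vals = rng.integers(-20, 21, size=(l, l)) * 0.05
    m = np.triu(vals, k=1)
    m = m + m.T
    np.fill_diagonal(m, 1.0)
    return m


class TestCorrelationMatrix:
    def test_identical_columns(self):
        col = np.random.default_rng(0).uniform(size=100)
        corr = prediction_correlation_matrix(np.column_stack([col, col]), ["a", "b"])
        assert corr.values[0, 1] == pytest.approx(1.0)

    def test_negation_about_half(self):
        col = np.random.default_rng(0).uniform(size=100)
        corr = prediction_correlation_matrix(np.column_stack([col, 1 - col]), ["a", "b"])
        assert corr.values[0, 1] == pytest.approx(-1.0)

    def test_iid_noise_near_zero(self):
        # oracle: sampling sd of r under independence ~ 1/sqrt(n) = 0.014
        rng = np.random.default_rng(1)
        oof = rng.uniform(size=(5000, 3))
        corr = prediction_correlation_matrix(oof, ["a", "b", "c"])
        off = corr.values[np.triu_indices(3, k=1)]
        assert np.all(np.abs(off) < 0.05)

    def test_constant_column_names_learner(self):
        oof = np.column_stack([np.full(10, 0.5), np.linspace(0, 1, 10)])
        with pytest.raises(ValueError, match="a"):
            prediction_correlation_matrix(oof, ["a", "b"])

    def test_missing_cells_rejected(self):
        oof = np.random.default_rng(0).uniform(size=(10, 2))
        oof[3, 1] = np.nan
        with pytest.raises(ValueError, match="b"):
            prediction_correlation_matrix(oof, ["a", "b"])

    def test_symmetry_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            _corr(["a", "b"], [[1.0, 0.5], [0.4, 1.0]])


class TestFindMaxPair:
    def test_argmax(self):
        m = _corr("abc", [[1, 0.85, 0.3], [0.85, 1, 0.1], [0.3, 0.1, 1]])
        pair, val = find_max_pair(m)
        assert pair == ("a", "b")
        assert val == pytest.approx(0.85)

    def test_all_equal_lexicographic(self):
        m = _corr("cab"[::-1], np.full((3, 3), 0.5) + np.eye(3) * 0.5)
        pair, _ = find_max_pair(m)
        assert pair == ("a", "b")

    def test_two_learners(self):
        m = _corr("xy", [[1, 0.2], [0.2, 1]])
        pair, val = find_max_pair(m)
        assert pair == ("x", "y")
        assert val == pytest.approx(0.2)


class TestRemovalIteration:
    def test_higher_average_removed(self):
        # pair (a,b) at 0.85; a has higher average -> a removed
        m = _corr(
            "abc",
            [[1.0, 0.85, 0.35], [0.85, 1.0, -0.05], [0.35, -0.05, 1.0]],
        )
        removed, rec = removal_iteration(m, RemovalConfig(), {})
        assert removed == "a"
        assert rec.avg_a == pytest.approx((0.85 + 0.35) / 2)
        assert rec.avg_b == pytest.approx((0.85 - 0.05) / 2)

    def test_below_threshold_none(self):
        m = _corr("ab", [[1, 0.70], [0.70, 1]])
        removed, rec = removal_iteration(m, RemovalConfig(), {})
        assert removed is None and rec is None

    def test_tie_removes_lower_cv_auc(self):
        m = _corr("ab", [[1, 0.9], [0.9, 1]])
        removed, rec = removal_iteration(m, RemovalConfig(), {"a": 0.6, "b": 0.8})
        assert removed == "a"
        assert rec.tie_break is not None


class TestRunRemoval:
    def test_identity_structure_all_survive(self):
        m = _corr("abcd", np.eye(4))
        trace = run_removal_matrix(m, RemovalConfig(), {})
        assert trace.iterations == []
        assert trace.survivors == ["a", "b", "c", "d"]

    def test_all_high_single_survivor(self):
        # oracle (hand simulation): every round removes one learner until one left
        vals = np.full((4, 4), 0.9)
        np.fill_diagonal(vals, 1.0)
        m = _corr("abcd", vals)
        trace = run_removal_matrix(m, RemovalConfig(), {"a": 1, "b": 2, "c": 3, "d": 4})
        assert len(trace.survivors) == 1
        assert len(trace.iterations) == 3

    def test_single_learner_trivial(self):
        trace = run_removal(np.random.uniform(size=(10, 1)), ["solo"], RemovalConfig(), {})
        assert trace.survivors == ["solo"]

    def test_trace_invariants(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            l = int(rng.integers(3, 7))
            m = _corr([f"L{i}" for i in range(l)], random_corr_matrix(l, rng))
            trace = run_removal_matrix(m, RemovalConfig(), {})
            assert len(trace.iterations) <= l - 1  # termination bound
            for rec in trace.iterations:
                assert rec.max_corr > 0.75
                rem_avg = rec.avg_a if rec.removed == rec.max_pair[0] else rec.avg_b
                oth_avg = rec.avg_b if rec.removed == rec.max_pair[0] else rec.avg_a
                assert rem_avg >= oth_avg
            # post-condition: survivor pairs all at or below threshold
            keep = [m.learner_names.index(s) for s in trace.survivors]
            sub = m.values[np.ix_(keep, keep)]
            if len(keep) > 1:
                assert sub[np.triu_indices(len(keep), k=1)].max() <= 0.75

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        l = int(rng.integers(3, 7))
        m = _corr([f"L{i}" for i in range(l)], random_corr_matrix(l, rng))
        lo = run_removal_matrix(m, RemovalConfig(threshold=0.6), {})
        hi = run_removal_matrix(m, RemovalConfig(threshold=0.8), {})
        assert len(hi.survivors) >= len(lo.survivors)

    def test_oracle_equivalence_sampled_grid(self):
        # 200 instances here; the full 1000-instance sweep runs in acceptance
        rng = np.random.default_rng(123)
        for _ in range(200):
            l = int(rng.choice([4, 5]))
            names = [f"L{i}" for i in range(l)]
            vals = random_corr_matrix(l, rng)
            aucs = {n: float(rng.uniform(0.5, 0.9)) for n in names}
            expected = brute_force_survivors(names, vals, 0.75, aucs)
            trace = run_removal_matrix(_corr(names, vals), RemovalConfig(), aucs)
            assert trace.survivors == expected
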