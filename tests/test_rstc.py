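"""Batch-min aggregation, per-predictor normalization, and decisions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgid.rstc import (
    BatchedScores,
    ScoreTensor,
    authenticate,
    batch_min,
    identify,
    normalize_scores,
)


def _tensor(values):
    values = np.asarray(values, dtype=float)
    P, I, W = values.shape
    return ScoreTensor(
        values,
        predictor_ids=[f"p{i}" for i in range(P)],
        subject_ids=[f"s{i}" for i in range(I)],
        window_ids=np.arange(W),
    )


def _rand_tensor(rng, P=4, I=4, W=24):
    return _tensor(rng.uniform(size=(P, I, W)))


class TestBatchMin:
    def test_minimum_of_block(self):
        t = _tensor(np.array([0.4, 0.2, 0.9]).reshape(1, 1, 3))
        out = batch_min(t, 3)
        assert out.values.shape == (1, 1, 1)
        assert out.values[0, 0, 0] == 0.2

    def test_b_one_is_identity(self):
        t = _rand_tensor(np.random.default_rng(0))
        assert np.array_equal(batch_min(t, 1).values, t.values)

    def test_matches_blockwise_brute_force(self):
        rng = np.random.default_rng(5)
        t = _rand_tensor(rng, W=23)
        out = batch_min(t, 4)
        for p in range(4):
            for i in range(4):
                for b in range(23 // 4):
                    expected = min(t.values[p, i, 4 * b + j] for j in range(4))
                    assert out.values[p, i, b] == expected

    def test_remainder_dropped_and_bounds(self):
        t = _rand_tensor(np.random.default_rng(1), W=10)
        assert batch_min(t, 3).values.shape[2] == 3
        with pytest.raises(ValueError):
            batch_min(t, 11)
        with pytest.raises(ValueError):
            batch_min(t, 0)

    @given(seed=st.integers(0, 1000), b_small=st.integers(1, 4))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_batch_size(self, seed, b_small):
        """Min over a superset of windows never exceeds min over the subset."""
        rng = np.random.default_rng(seed)
        t = _rand_tensor(rng, W=24)
        big = batch_min(t, 2 * b_small).values
        small = batch_min(t, b_small).values
        # batch b of the larger size covers batches 2b, 2b+1 of the smaller
        for b in range(big.shape[2]):
            assert np.all(big[:, :, b] <= small[:, :, 2 * b] + 1e-15)
            assert np.all(big[:, :, b] <= small[:, :, 2 * b + 1] + 1e-15)


class TestNormalization:
    def test_direct_column_example(self):
        t = BatchedScores(np.array([0.2, 0.6, 1.0]).reshape(3, 1, 1), 1, list("abc"), ["s"])
        out = normalize_scores(t).values[:, 0, 0]
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_column_bounds(self):
        rng = np.random.default_rng(2)
        t = BatchedScores(rng.uniform(size=(5, 3, 8)), 1, list("abcde"), list("xyz"))
        out = normalize_scores(t).values
        assert np.allclose(out.min(axis=0), 0.0)
        assert np.allclose(out.max(axis=0), 1.0)

    def test_degenerate_all_equal_column(self):
        t = BatchedScores(np.full((2, 1, 1), 0.5), 1, ["a", "b"], ["s"])
        assert np.allclose(normalize_scores(t).values, 0.0)

    def test_single_predictor_rejected(self):
        t = BatchedScores(np.full((1, 1, 3), 0.5), 1, ["a"], ["s"])
        with pytest.raises(ValueError):
            normalize_scores(t)

    def test_idempotent_on_normalized_columns(self):
        rng = np.random.default_rng(3)
        t = BatchedScores(rng.uniform(size=(4, 3, 6)), 1, list("abcd"), list("xyz"))
        once = normalize_scores(t)
        twice = normalize_scores(once)
        assert np.allclose(once.values, twice.values)


class TestIdentification:
    def test_argmin_and_tie_rule(self):
        t = BatchedScores(np.array([[0.0], [0.5], [1.0]]).reshape(3, 1, 1), 1, list("abc"), ["s"])
        assert identify(t)[0, 0] == 0
        tie = BatchedScores(np.array([[0.0], [0.0], [1.0]]).reshape(3, 1, 1), 1, list("abc"), ["s"])
        assert identify(tie)[0, 0] == 0  # lowest index wins ties

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        t = BatchedScores(rng.uniform(size=(5, 4, 9)), 1, list("abcde"), list("wxyz"))
        out = identify(t)
        for i in range(4):
            for b in range(9):
                best, best_p = np.inf, -1
                for p in range(5):
                    if t.values[p, i, b] < best:
                        best, best_p = t.values[p, i, b], p
                assert out[i, b] == best_p

    def test_dominated_true_predictor_always_wins(self):
        """If the true predictor is strictly lowest on every window, every
        batch size identifies it."""
        rng = np.random.default_rng(6)
        v = rng.uniform(0.3, 1.0, size=(4, 1, 24))
        v[2, 0, :] = rng.uniform(0.0, 0.25, size=24)  # strictly dominated column
        t = _tensor(np.tile(v, (1, 3, 1))[:, :1, :])
        for B in (1, 2, 4, 8, 24):
            s = normalize_scores(batch_min(t, B))
            assert np.all(identify(s)[0] == 2)


class TestAuthentication:
    def test_boundary_accepts(self):
        t = BatchedScores(np.array([[[0.3]], [[0.6]]]), 1, ["a", "b"], ["s"])
        assert authenticate(t, 0, 0.3)[0, 0] == 1  # score == delta accepted

    def test_extreme_thresholds(self):
        rng = np.random.default_rng(7)
        t = BatchedScores(rng.uniform(size=(3, 2, 5)), 1, list("abc"), ["s", "t"])
        assert np.all(authenticate(t, 1, 1.0) == 1)
        assert np.all(authenticate(t, 1, -0.01) == 0)

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(8)
        t = BatchedScores(rng.uniform(size=(3, 4, 7)), 1, list("abc"), list("wxyz"))
        delta = 0.42
        for p in range(3):
            bits = authenticate(t, p, delta)
            for i in range(4):
                for b in range(7):
                    assert bits[i, b] == (1 if t.values[p, i, b] <= delta else 0)

    def test_unknown_identity_rejected(self):
        t = BatchedScores(np.zeros((2, 1, 1)), 1, ["a", "b"], ["s"])
        with pytest.raises(ValueError):
            authenticate(t, "nobody", 0.5)
        with pytest.raises(ValueError):
            authenticate(t, 5, 0.5)


def test_score_tensor_validates_range():
    with pytest.raises(ValueError):
        _tensor(np.full((2, 2, 2), 1.5))
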