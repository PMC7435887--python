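"""Recurrent next-sample predictors: architecture, training, scoring."""

import numpy as np
import pytest

from ecgid.preprocess import segment_windows
from ecgid.rnn import (
    PredictorBank,
    RNNSubjectPredictor,
    build_predictor,
    error_score_tensor,
    prediction_error,
    rnn_score_tensor,
)
from ecgid._nn import softmax


def _predictor(**kw):
    defaults = dict(sd=16, embed_dim=4, hidden=8, epochs=0, seed=0)
    defaults.update(kw)
    return build_predictor(**defaults)


class TestArchitecture:
    def test_parameter_count_closed_form(self):
        sd, e, h = 512, 32, 64
        pred = build_predictor(sd=sd, embed_dim=e, hidden=h)
        gru = lambda d: d * 3 * h + 3 * h * h + 3 * h  # W + (U_zr, U_n) + bias
        expected = sd * e + gru(e) + gru(h) + gru(h) + (h * sd + sd)
        assert pred.n_parameters_ == expected

    def test_same_seed_identical_initialization(self):
        a, b = _predictor(seed=7), _predictor(seed=7)
        for la, lb in zip(a.model_.layers, b.model_.layers):
            for k in la.params:
                assert np.array_equal(la.params[k], lb.params[k])

    def test_forward_pass_softmax_normalization(self):
        pred = _predictor()
        x = np.random.default_rng(0).integers(0, 16, size=(3, 20))
        p, yhat = pred._forward_expectation(x, train=False)
        assert p.shape == (3, 20, 16)
        assert np.allclose(p.sum(axis=-1), 1.0)
        assert yhat.shape == (3, 20)
        assert np.all((yhat >= 0) & (yhat <= 15))

    def test_three_gru_layers_enforced(self):
        with pytest.raises(ValueError):
            RNNSubjectPredictor(n_gru=2).build()


class TestTraining:
    def test_zero_epochs_is_no_op(self):
        x = np.random.default_rng(1).integers(0, 16, size=(8, 32))
        trained = RNNSubjectPredictor(sd=16, embed_dim=4, hidden=8, epochs=0, seed=3).fit(x)
        fresh = _predictor(seed=3)
        for lt, lf in zip(trained.model_.layers, fresh.model_.layers):
            for k in lt.params:
                assert np.array_equal(lt.params[k], lf.params[k])
        assert trained.loss_trace_ == []

    def test_loss_trace_length_equals_epochs(self):
        x = np.random.default_rng(2).integers(0, 8, size=(6, 24))
        pred = RNNSubjectPredictor(
            sd=8, embed_dim=4, hidden=8, epochs=3, val_fraction=0.0, seed=0
        ).fit(x)
        assert len(pred.loss_trace_) == 3

    def test_learns_constant_period_square_wave(self):
        """Deterministic periodic input: final loss < 1% of the initial loss."""
        period = np.array(([0] * 8 + [7] * 8), dtype=int)
        sig = np.tile(period, 40)
        wins = segment_windows(sig, 64, 0.0).windows
        pred = RNNSubjectPredictor(
            sd=8, embed_dim=8, hidden=16, epochs=200, lr=1e-2, val_fraction=0.0, seed=1
        ).fit(wins)
        assert pred.loss_trace_[-1] < 0.01 * pred.loss_trace_[0]

    def test_mixed_subject_windows_rejected(self):
        ws = segment_windows(np.arange(64) % 8, 16, 0.0)
        ws.labels = np.array(["A", "B", "A", "B"])
        with pytest.raises(ValueError):
            RNNSubjectPredictor(sd=8).fit(ws)


class TestPredictionError:
    def test_perfect_oracle_gives_zero(self):
        y = np.arange(10.0)
        assert prediction_error(y, y) == 0.0

    def test_constant_offset_squares(self):
        y = np.random.default_rng(0).normal(size=50)
        assert prediction_error(y + 3.0, y) == pytest.approx(9.0)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            yhat, y = rng.normal(size=30), rng.normal(size=30)
            brute = sum((a - b) ** 2 for a, b in zip(yhat, y)) / 30
            assert prediction_error(yhat, y) == pytest.approx(brute, abs=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            prediction_error(np.ones(5), np.ones(6))

    def test_predictor_error_is_mse_of_expectation(self):
        """Windowed error equals the hand-computed MSE of the softmax
        expectation against the one-sample-shifted window."""
        pred = _predictor(sd=8, embed_dim=4, hidden=8)
        x = np.random.default_rng(3).integers(0, 8, size=(4, 20))
        pred.n_features_in_ = 20
        errs = pred.prediction_error(x)
        logits = pred.model_.forward(x[:, :-1], train=False)
        yhat = softmax(logits) @ np.arange(8.0)
        manual = ((yhat - x[:, 1:]) ** 2).mean(axis=1)
        assert np.allclose(errs, manual)


class TestScoreTensor:
    def test_direct_column_example(self):
        assert np.allclose(error_score_tensor(np.array([[2.0], [4.0]])), [[0.5], [1.0]])

    def test_single_predictor_scores_one(self):
        assert np.allclose(error_score_tensor(np.array([[3.0, 7.0]])), 1.0)

    def test_per_column_max_is_one(self):
        rng = np.random.default_rng(2)
        s = error_score_tensor(rng.uniform(0.1, 5.0, size=(6, 40)))
        assert np.allclose(s.max(axis=0), 1.0)
        assert np.all((s > 0) & (s <= 1))

    def test_all_zero_column_degenerates_to_zero(self):
        e = np.array([[0.0, 1.0], [0.0, 2.0]])
        s = error_score_tensor(e)
        assert np.allclose(s[:, 0], 0.0)
        assert np.allclose(s[:, 1], [0.5, 1.0])

    def test_matches_brute_force_on_random_errors(self):
        rng = np.random.default_rng(3)
        e = rng.uniform(0.01, 10, size=(5, 30))
        s = error_score_tensor(e)
        for i in range(30):
            m = max(e[p, i] for p in range(5))
            for p in range(5):
                assert s[p, i] == pytest.approx(e[p, i] / m, abs=1e-12)


class TestBank:
    def test_bank_scores_full_tensor(self):
        rng = np.random.default_rng(4)
        sigs = {s: rng.integers(0, 8, size=400) for s in ("A", "B")}
        parts = []
        for s, sig in sigs.items():
            w = segment_windows(sig, 32, 0.0, subject_id=s, sd=8)
            parts.append(w)
        from ecgid.preprocess import _concat

        wset = _concat(parts)
        bank = PredictorBank.fit(wset, sd=8, embed_dim=4, hidden=8, epochs=1)
        tensor = rnn_score_tensor(bank, wset)
        assert tensor.values.shape[0] == 2 and tensor.values.shape[1] == 2
        assert tensor.predictor_ids == ["A", "B"]
        assert np.allclose(tensor.values.max(axis=0), 1.0)

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            PredictorBank({})
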