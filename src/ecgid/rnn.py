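"""Per-subject recurrent next-sample predictors and their similarity scores.

One :class:`RNNSubjectPredictor` is enrolled per subject: an embedding matrix
over the ``SD`` quantized amplitude levels feeds three stacked GRU layers and
a dense layer producing, at every time step, a distribution over the next
sample's level.  The point prediction is the softmax expectation
``yhat_n = sum_k k P(k)``, which keeps the mean-squared next-sample loss

    e = (1 / W) * sum_n (yhat_n - y_n)^2,      y_n = x_{n+1}

differentiable end-to-end; the same quantity serves as training loss
(RMSProp) and as the window prediction error at test time.  The biometric
premise is that a predictor trained on subject A incurs a larger prediction
error on any other subject's signal than on A's own.

Scores: for each test window ``w`` of true subject ``i`` the error of every
enrolled predictor ``p`` is normalized by the worst predictor on that window,

    S(p, i, w) = e(p, i, w) / max_p' e(p', i, w),

so every column has maximum exactly 1 and the best predictor the smallest
score.  Because each predictor is trained independently on its own subject,
enrolling a new subject never requires retraining the existing bank.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._nn import GRU, Dense, Embedding, RMSProp, Sequential, softmax
from .preprocess import QuantizedWindowSet
from .rstc import ScoreTensor, assemble_score_tensor

__all__ = [
    "RNNSubjectPredictor",
    "PredictorBank",
    "build_predictor",
    "train_predictor",
    "prediction_error",
    "rnn_score_tensor",
]


class RNNSubjectPredictor(BaseEstimator):
    """Next-sample predictor for one enrolled subject.

    Parameters
    ----------
    sd : vocabulary size (quantization levels); must match the preprocessing.
    embed_dim, hidden : embedding width and hidden units per GRU layer.
    n_gru : stacked GRU layers (the architecture fixes this at 3).
    lr, epochs, batch_windows : RMSProp step size, training epochs, windows
        per mini-batch.
    val_fraction, patience : early-stopping hold-out and tolerance (epochs);
        the best-validation parameters are restored after training.
    """

    def __init__(
        self,
        sd: int = 512,
        embed_dim: int = 32,
        hidden: int = 64,
        n_gru: int = 3,
        lr: float = 1e-3,
        epochs: int = 30,
        batch_windows: int = 32,
        val_fraction: float = 0.1,
        patience: int = 5,
        seed: int = 0,
    ) -> None:
        self.sd = sd
        self.embed_dim = embed_dim
        self.hidden = hidden
        self.n_gru = n_gru
        self.lr = lr
        self.epochs = epochs
        self.batch_windows = batch_windows
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed

    # ---------------------------------------------------------------- build

    def build(self) -> "RNNSubjectPredictor":
        """Instantiate the network (deterministic in ``seed``) without training."""
        if self.n_gru != 3:
            raise ValueError("the architecture uses exactly three GRU layers")
        rng = np.random.default_rng(self.seed)
        layers = [Embedding(self.sd, self.embed_dim, rng)]
        d_in = self.embed_dim
        for _ in range(self.n_gru):
            layers.append(GRU(d_in, self.hidden, rng))
            d_in = self.hidden
        layers.append(Dense(self.hidden, self.sd, rng))
        self.model_ = Sequential(layers)
        self.loss_trace_ = []
        return self

    @property
    def n_parameters_(self) -> int:
        return self.model_.n_parameters()

    # -------------------------------------------------------------- helpers

    def _check_windows(self, X) -> np.ndarray:
        if isinstance(X, QuantizedWindowSet):
            if len(set(X.labels.tolist())) > 1:
                raise ValueError("a subject predictor must be fit on ONE subject's windows")
            X = X.windows
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("expected (n_windows, W) integer windows")
        if X.min() < 0 or X.max() > self.sd - 1:
            raise ValueError("window values must lie in {0..SD-1}")
        return X.astype(int)

    def _forward_expectation(
        self, xb: np.ndarray, train: bool
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return softmax probabilities (B, T, SD) and expectations (B, T)."""
        logits = self.model_.forward(xb, train=train)
        p = softmax(logits, axis=-1)
        yhat = p @ self._levels
        return p, yhat

    @property
    def _levels(self) -> np.ndarray:
        return np.arange(self.sd, dtype=float)

    # ------------------------------------------------------------------ fit

    def fit(self, X, y=None) -> "RNNSubjectPredictor":
        """Train on one subject's quantized windows (input shifted by one
        sample is the target)."""
        X = self._check_windows(X)
        self.build()
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.seed + 1)
        n = len(X)
        n_val = int(round(self.val_fraction * n)) if n >= 10 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        opt = RMSProp(self.model_, lr=self.lr)
        best_val, best_state, bad = np.inf, None, 0
        for _epoch in range(self.epochs):
            order = rng.permutation(tr_idx)
            losses = []
            for k in range(0, len(order), self.batch_windows):
                batch = X[order[k : k + self.batch_windows]]
                xb, yb = batch[:, :-1], batch[:, 1:].astype(float)
                p, yhat = self._forward_expectation(xb, train=True)
                resid = yhat - yb
                losses.append(float((resid**2).mean()))
                # d loss / d yhat, then through the softmax expectation
                dyhat = 2.0 * resid / resid.size
                dlogits = p * (self._levels - yhat[..., None]) * dyhat[..., None]
                self.model_.zero_grad()
                self.model_.backward(dlogits)
                opt.step()
            self.loss_trace_.append(float(np.mean(losses)) if losses else np.nan)
            if n_val:
                val = float(np.mean(self.prediction_error(X[val_idx])))
                if val < best_val - 1e-12:
                    best_val, best_state, bad = val, self.model_.get_state(), 0
                else:
                    bad += 1
                    if bad > self.patience:
                        break
        if best_state is not None:
            self.model_.set_state(best_state)
        return self

    # ---------------------------------------------------------------- score

    def prediction_error(self, X, batch: int = 64) -> np.ndarray:
        """Mean-squared next-sample error per window, on the quantized scale."""
        X = self._check_windows(X)
        if X.shape[1] != getattr(self, "n_features_in_", X.shape[1]):
            raise ValueError("window length differs from the training length")
        errs = np.empty(len(X))
        for k in range(0, len(X), batch):
            b = X[k : k + batch]
            xb, yb = b[:, :-1], b[:, 1:].astype(float)
            _, yhat = self._forward_expectation(xb, train=False)
            errs[k : k + batch] = ((yhat - yb) ** 2).mean(axis=1)
        return errs


def build_predictor(**spec) -> RNNSubjectPredictor:
    """Construct and initialize a predictor from keyword hyper-parameters."""
    return RNNSubjectPredictor(**spec).build()


def train_predictor(
    predictor: RNNSubjectPredictor, windows, **fit_kwargs
) -> RNNSubjectPredictor:
    return predictor.fit(windows, **fit_kwargs)


def prediction_error(yhat: np.ndarray, y: np.ndarray) -> float:
    """The window prediction error ``(1/W) sum (yhat_n - y_n)^2`` for given
    predicted and true (shifted) samples."""
    yhat, y = np.asarray(yhat, dtype=float), np.asarray(y, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError("prediction and target must have equal length")
    return float(((yhat - y) ** 2).mean())


def error_score_tensor(e: np.ndarray) -> np.ndarray:
    """Max-normalize prediction errors columnwise: ``S = e / max_p e``.

    ``e`` is (P, n_windows); each column's maximum maps to exactly 1.
    All-zero columns are degenerate and map to 0.
    """
    e = np.asarray(e, dtype=float)
    col_max = e.max(axis=0)
    s = np.zeros_like(e)
    np.divide(e, col_max, out=s, where=col_max > 0)
    return s


class PredictorBank:
    """One trained :class:`RNNSubjectPredictor` per enrolled subject."""

    def __init__(self, predictors: dict[str, RNNSubjectPredictor]):
        if not predictors:
            raise ValueError("empty predictor bank")
        self.predictors = dict(sorted(predictors.items()))

    @property
    def subject_ids(self) -> list[str]:
        return list(self.predictors)

    @classmethod
    def fit(
        cls, train_windows: QuantizedWindowSet, seed: int = 0, **spec
    ) -> "PredictorBank":
        """Train one predictor per subject present in ``train_windows``."""
        bank = {}
        for j, subj in enumerate(train_windows.subjects):
            pred = RNNSubjectPredictor(seed=seed + j, **spec)
            pred.fit(train_windows.for_subject(subj))
            bank[subj] = pred
        return cls(bank)

    def score_tensor(self, test_windows: QuantizedWindowSet) -> ScoreTensor:
        return rnn_score_tensor(self, test_windows)


def rnn_score_tensor(bank: PredictorBank, test_windows: QuantizedWindowSet) -> ScoreTensor:
    """Score every test window with every enrolled predictor (max-normalized
    prediction errors; each (i, w) column has maximum exactly 1).

    Columns where every predictor has zero error are degenerate and set to 0.
    """
    pred_ids = bank.subject_ids
    per_subject: dict[str, np.ndarray] = {}
    for subj in test_windows.subjects:
        wins = test_windows.for_subject(subj)
        e = np.stack([bank.predictors[p].prediction_error(wins.windows) for p in pred_ids])
        per_subject[subj] = error_score_tensor(e)
    return assemble_score_tensor(per_subject, pred_ids)
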