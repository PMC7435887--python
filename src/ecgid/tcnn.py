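"""Two-stream dilated temporal convolutional classifier.

One stream consumes the whole preprocessed window (non-fiducial); the other
consumes the R-centered single-cycle sub-segment (fiducial) and has two fewer
convolutional blocks.  Every block is a causal dilated 1-D convolution with
24 kernels of size 4, batch normalization, and ReLU; each stream ends in a
256-unit fully connected layer and a per-subject logit layer.  The streams
are trained independently with Adam on categorical cross-entropy and fused at
score time by the sum rule on their logit vectors.

The per-layer dilation schedule defaults to powers of two descending to 1
(e.g. ``[32, 16, 8, 4, 2, 1]`` for six layers); the stack's receptive field
is ``1 + (kernel - 1) * sum(dilations)`` and must not exceed the input
length.  Scores follow the inverted-normalized-output rule

    S(p, i, w) = 1 - o(p, i, w) / max_p' o(p', i, w),

computed on softmax outputs (guaranteeing non-negativity and a well-defined
maximum), so the top class gets score 0.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import (
    Adam,
    BatchNorm1d,
    Conv1dDilated,
    Dense,
    Flatten,
    ReLU,
    Sequential,
    softmax,
    softmax_cross_entropy,
)
from .preprocess import QuantizedWindowSet
from .rstc import ScoreTensor, assemble_score_tensor

__all__ = [
    "TwoStreamTCNN",
    "build_stream",
    "fuse_logits",
    "tcnn_score_tensor",
    "receptive_field",
    "default_dilations",
]


def default_dilations(n_layers: int) -> list[int]:
    """Powers of two descending to 1: ``[2^(n-1), ..., 2, 1]``."""
    return [2**i for i in range(n_layers - 1, -1, -1)]


def receptive_field(kernel: int, dilations: list[int]) -> int:
    return 1 + (kernel - 1) * int(sum(dilations))


def build_stream(
    input_len: int,
    n_classes: int,
    dilations: list[int],
    kernels: int = 24,
    kernel_size: int = 4,
    fc_units: int = 256,
    rng: np.random.Generator | None = None,
) -> Sequential:
    """Stack conv(24 kernels, size 4, dilated)->BN->ReLU blocks, then
    FC(fc_units)->ReLU->FC(n_classes) logits."""
    rf = receptive_field(kernel_size, dilations)
    if rf > input_len:
        raise ValueError(
            f"receptive field {rf} samples exceeds input length {input_len}; "
            "reduce the dilation schedule or enlarge the window"
        )
    rng = rng if rng is not None else np.random.default_rng(0)
    layers = []
    c_in = 1
    for d in dilations:
        layers += [
            Conv1dDilated(c_in, kernels, kernel_size, d, rng),
            BatchNorm1d(kernels),
            ReLU(),
        ]
        c_in = kernels
    layers += [
        Flatten(),
        Dense(kernels * input_len, fc_units, rng),
        ReLU(),
        Dense(fc_units, n_classes, rng),
    ]
    return Sequential(layers)


def fuse_logits(o_nonfid: np.ndarray, o_fid: np.ndarray) -> np.ndarray:
    """Sum-rule fusion of the two streams' logit vectors."""
    o_nonfid, o_fid = np.asarray(o_nonfid, float), np.asarray(o_fid, float)
    if o_nonfid.shape != o_fid.shape:
        raise ValueError("logit vectors must have equal length")
    return o_nonfid + o_fid


class TwoStreamTCNN(BaseEstimator, ClassifierMixin):
    """Subject classifier over preprocessed ECG windows.

    Parameters
    ----------
    n_layers_nonfid : convolutional blocks in the non-fiducial stream; the
        fiducial stream always has two fewer.
    dilations_nonfid, dilations_fid : per-layer dilation factors; default
        powers of two descending to 1.
    kernels, kernel_size, fc_units : 24 kernels of size 4 and a 256-unit
        dense layer, as in the reference architecture.
    lr, epochs, batch_size : Adam step size, epochs, windows per mini-batch.
    val_fraction, patience : early stopping on a held-out slice.
    """

    def __init__(
        self,
        n_layers_nonfid: int = 6,
        dilations_nonfid: list[int] | None = None,
        dilations_fid: list[int] | None = None,
        kernels: int = 24,
        kernel_size: int = 4,
        fc_units: int = 256,
        lr: float = 1e-3,
        epochs: int = 15,
        batch_size: int = 64,
        val_fraction: float = 0.1,
        patience: int = 3,
        seed: int = 0,
    ) -> None:
        self.n_layers_nonfid = n_layers_nonfid
        self.dilations_nonfid = dilations_nonfid
        self.dilations_fid = dilations_fid
        self.kernels = kernels
        self.kernel_size = kernel_size
        self.fc_units = fc_units
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed

    # -------------------------------------------------------------- helpers

    def _schedules(self) -> tuple[list[int], list[int]]:
        if self.n_layers_nonfid < 3:
            raise ValueError("need >= 3 non-fiducial layers (fiducial stream has two fewer)")
        non = self.dilations_nonfid or default_dilations(self.n_layers_nonfid)
        fid = self.dilations_fid or default_dilations(self.n_layers_nonfid - 2)
        if len(fid) != len(non) - 2:
            raise ValueError("fiducial stream must have two fewer blocks than non-fiducial")
        return list(non), list(fid)

    def _unpack(self, X) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
        if isinstance(X, QuantizedWindowSet):
            return X.windows.astype(float), X.cycles, X.has_cycle
        return np.asarray(X, dtype=float), None, None

    # ------------------------------------------------------------------ fit

    def fit(self, X, y=None) -> "TwoStreamTCNN":
        """Train both streams independently on labeled windows.

        ``X`` is a :class:`QuantizedWindowSet` (real-valued path, with cycle
        sub-segments attached) or an ``(n, W)`` array with explicit ``y``.
        """
        windows, cycles, has_cycle = self._unpack(X)
        if y is None:
            if not isinstance(X, QuantizedWindowSet):
                raise ValueError("y is required when X is a plain array")
            y = X.labels
        y = np.asarray(y)
        self.classes_ = np.array(sorted(set(y.tolist())))
        counts = {c: int((y == c).sum()) for c in self.classes_}
        empty = [c for c, n in counts.items() if n == 0]
        if len(self.classes_) < 2:
            raise ValueError("need at least two subjects to classify")
        if empty:
            raise ValueError(f"subjects with zero windows: {empty}")
        y_idx = np.searchsorted(self.classes_, y)

        non_sched, fid_sched = self._schedules()
        rng = np.random.default_rng(self.seed)
        n_cls = len(self.classes_)
        self.nonfid_ = build_stream(
            windows.shape[1], n_cls, non_sched, self.kernels, self.kernel_size,
            self.fc_units, rng,
        )
        self.loss_trace_ = {"nonfid": [], "fid": []}
        self._train_stream(self.nonfid_, windows, y_idx, "nonfid", rng)

        self.fid_ = None
        if cycles is not None and has_cycle is not None and has_cycle.any():
            self.fid_ = build_stream(
                cycles.shape[1], n_cls, fid_sched, self.kernels, self.kernel_size,
                self.fc_units, rng,
            )
            self._train_stream(self.fid_, cycles[has_cycle], y_idx[has_cycle], "fid", rng)
        return self

    def _train_stream(
        self,
        net: Sequential,
        data: np.ndarray,
        y_idx: np.ndarray,
        name: str,
        rng: np.random.Generator,
    ) -> None:
        data = data[:, None, :]  # (n, 1, T) channel-first
        n = len(data)
        n_val = int(round(self.val_fraction * n)) if n >= 20 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        opt = Adam(net, lr=self.lr)
        best_val, best_state, bad = np.inf, None, 0
        for _epoch in range(self.epochs):
            order = rng.permutation(tr_idx)
            losses = []
            for k in range(0, len(order), self.batch_size):
                idx = order[k : k + self.batch_size]
                if len(idx) < 2:
                    continue  # batch statistics need >= 2 windows
                logits = net.forward(data[idx], train=True)
                loss, dlogits = softmax_cross_entropy(logits, y_idx[idx])
                losses.append(loss)
                net.zero_grad()
                net.backward(dlogits)
                opt.step()
            self.loss_trace_[name].append(float(np.mean(losses)) if losses else np.nan)
            if n_val:
                vlog = self._forward_eval(net, data[val_idx])
                vloss, _ = softmax_cross_entropy(vlog, y_idx[val_idx])
                if vloss < best_val - 1e-12:
                    best_val, best_state, bad = vloss, net.get_state(), 0
                else:
                    bad += 1
                    if bad > self.patience:
                        break
        if best_state is not None:
            net.set_state(best_state)
        self._calibrate_batchnorm(net, data[tr_idx])

    def _calibrate_batchnorm(self, net: Sequential, data: np.ndarray) -> None:
        """Recompute batch-norm statistics over the training data with the
        final weights; running averages lag the weights they normalize for,
        and the mismatch compounds through the stack at eval time."""
        bns = [l for l in net.layers if isinstance(l, BatchNorm1d)]
        if not bns:
            return
        means: dict[int, list] = {id(l): [] for l in bns}
        variances: dict[int, list] = {id(l): [] for l in bns}
        for k in range(0, len(data), self.batch_size):
            b = data[k : k + self.batch_size]
            if len(b) < 2:
                continue
            net.forward(b, train=True)
            for l in bns:
                means[id(l)].append(l._batch_mean)
                variances[id(l)].append(l._batch_var)
        for l in bns:
            if means[id(l)]:
                l.running_mean = np.mean(means[id(l)], axis=0)
                l.running_var = np.mean(variances[id(l)], axis=0)

    @staticmethod
    def _forward_eval(net: Sequential, data: np.ndarray, batch: int = 256) -> np.ndarray:
        outs = [net.forward(data[k : k + batch], train=False) for k in range(0, len(data), batch)]
        return np.concatenate(outs)

    # ---------------------------------------------------------------- infer

    def decision_function(self, X) -> np.ndarray:
        """Fused logits (n, I); windows without a detected R peak are scored
        by the non-fiducial stream alone (fusion with a zero vector)."""
        windows, cycles, has_cycle = self._unpack(X)
        logits = self._forward_eval(self.nonfid_, windows[:, None, :])
        if self.fid_ is not None and cycles is not None and has_cycle is not None:
            fid_logits = np.zeros_like(logits)
            if has_cycle.any():
                fid_logits[has_cycle] = self._forward_eval(
                    self.fid_, cycles[has_cycle][:, None, :]
                )
            logits = fuse_logits(logits, fid_logits)
        return logits

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X), axis=-1)

    def score_tensor(self, test_windows: QuantizedWindowSet) -> ScoreTensor:
        """Similarity scores from the fused streams for every test window."""
        per_subject = {}
        for subj in test_windows.subjects:
            wins = test_windows.for_subject(subj)
            o = softmax(self.decision_function(wins), axis=-1)  # (n_w, I)
            per_subject[subj] = tcnn_score_tensor(o).T  # (I, n_w)
        return assemble_score_tensor(per_subject, list(self.classes_))


def tcnn_score_tensor(o: np.ndarray) -> np.ndarray:
    """Map non-negative output vectors to scores ``1 - o / max(o)`` rowwise.

    ``o`` is (n_windows, I); the argmax class of each row gets score 0.
    All-equal rows are degenerate and map to all zeros.
    """
    o = np.asarray(o, dtype=float)
    if o.ndim == 1:
        o = o[None, :]
    if (o < 0).any():
        raise ValueError("scores require non-negative outputs (softmax the logits first)")
    mx = o.max(axis=1, keepdims=True)
    s = np.zeros_like(o)
    np.divide(o, mx, out=s, where=mx > 0)
    out = 1.0 - s
    out[(o == mx).all(axis=1)] = 0.0  # all-equal rows: degenerate
    return out
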