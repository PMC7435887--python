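"""Relative Score Threshold Classifier (RSTC).

Window-level similarity scores ``S(p, i, w)`` — predictor ``p``, true subject
``i``, window ``w``, all in [0, 1] with 0 the most-probable class — are turned
into decisions in three steps:

1. **batch-min aggregation**: consecutive non-overlapping blocks of ``B``
   windows are collapsed to their minimum,
   ``S~(p, i, b) = min_w-in-block S(p, i, w)`` (trailing remainder dropped);
2. **per-predictor normalization**: each (i, b) column is min-max normalized
   over predictors, ``S-(p, i, b) = (S~ - min_p S~) / (max_p S~ - min_p S~)``,
   so the best predictor sits at 0 and the worst at 1;
3. **decision**: identification picks ``argmin_p S-(p, i, b)`` (ties to the
   lowest predictor index, deterministically); authentication of a claimed
   identity ``p`` accepts iff ``S-(p, i, b) <= delta``.

Columns where every predictor ties normalize to all zeros; identification of
such a column falls to the tie rule and the event is counted in
``ScoreTensor``-level logs rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreTensor",
    "BatchedScores",
    "assemble_score_tensor",
    "batch_min",
    "normalize_scores",
    "identify",
    "authenticate",
]


@dataclass
class ScoreTensor:
    """Similarity scores ``values[p, i, w]`` in [0, 1]."""

    values: np.ndarray
    predictor_ids: list[str]
    subject_ids: list[str]
    window_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("score tensor must be (P, I, W)")
        P, I, W = self.values.shape
        if P != len(self.predictor_ids) or I != len(self.subject_ids):
            raise ValueError("id lists inconsistent with tensor shape")
        if len(self.window_ids) != W:
            raise ValueError("window id list inconsistent with tensor shape")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]


@dataclass
class BatchedScores:
    """Batch-aggregated scores ``values[p, i, b]`` with batch size ``B``."""

    values: np.ndarray
    B: int
    predictor_ids: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("batched scores must be (P, I, n_batches)")


def assemble_score_tensor(
    per_subject: dict[str, np.ndarray], predictor_ids: list[str]
) -> ScoreTensor:
    """Stack per-subject (P, n_i) score matrices into a dense (P, I, W) tensor.

    Subjects may contribute different window counts (different record lengths
    survive rejection differently); the tensor is truncated to the common
    minimum so downstream batching is uniform.
    """
    subject_ids = sorted(per_subject)
    n_min = min(per_subject[s].shape[1] for s in subject_ids)
    values = np.stack([per_subject[s][:, :n_min] for s in subject_ids], axis=1)
    return ScoreTensor(
        values=values,
        predictor_ids=list(predictor_ids),
        subject_ids=subject_ids,
        window_ids=np.arange(n_min),
    )


def batch_min(S: ScoreTensor, B: int) -> BatchedScores:
    """Collapse consecutive blocks of ``B`` windows to their minimum."""
    if B < 1:
        raise ValueError("batch size must be >= 1")
    W = S.n_windows
    if B > W:
        raise ValueError(f"batch size {B} exceeds window count {W}")
    n_batches = W // B
    v = S.values[:, :, : n_batches * B]
    out = v.reshape(v.shape[0], v.shape[1], n_batches, B).min(axis=3)
    return BatchedScores(
        values=out, B=B, predictor_ids=S.predictor_ids, subject_ids=S.subject_ids
    )


def normalize_scores(S_batched: BatchedScores) -> BatchedScores:
    """Min-max normalize each (i, b) column over predictors.

    Non-degenerate columns end with min 0 and max 1; all-equal columns map to
    all zeros (logged), which defers the decision to the tie rule.
    """
    v = S_batched.values
    if v.shape[0] < 2:
        raise ValueError("normalization needs at least two predictors")
    lo = v.min(axis=0, keepdims=True)
    hi = v.max(axis=0, keepdims=True)
    span = hi - lo
    out = np.zeros_like(v)
    np.divide(v - lo, span, out=out, where=span > 0)
    n_degenerate = int((span == 0).sum())
    if n_degenerate:
        logger.info("normalize_scores: %d degenerate all-equal columns -> 0", n_degenerate)
    return BatchedScores(
        values=out,
        B=S_batched.B,
        predictor_ids=S_batched.predictor_ids,
        subject_ids=S_batched.subject_ids,
    )


def identify(S_norm: BatchedScores) -> np.ndarray:
    """Predicted predictor index per (subject, batch): argmin over predictors
    (np.argmin already breaks ties toward the lowest index)."""
    return np.argmin(S_norm.values, axis=0)


def authenticate(S_norm: BatchedScores, claimed: int | str, delta: float) -> np.ndarray:
    """Authentication bits for a claimed identity: accept iff score <= delta."""
    if isinstance(claimed, str):
        if claimed not in S_norm.predictor_ids:
            raise ValueError(f"unknown claimed identity {claimed!r}")
        p = S_norm.predictor_ids.index(claimed)
    else:
        p = int(claimed)
        if not 0 <= p < S_norm.values.shape[0]:
            raise ValueError(f"unknown claimed identity index {p}")
    return (S_norm.values[p] <= delta).astype(int)
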