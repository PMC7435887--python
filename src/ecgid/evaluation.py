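"""Biometric evaluation: identification metrics, per-individual ROC/EER,
and batch-size sweeps.

Identification is scored with a confusion matrix (rows true subject, columns
predicted), overall accuracy, and macro-averaged per-class sensitivity
``TP / (TP + FN)`` and specificity ``TN / (TN + FP)``.

Authentication is scored per enrolled individual ``p``: genuine scores are
the normalized batch scores ``S-(p, p, b)`` of the individual's own batches,
impostor scores are ``S-(p, i != p, b)``.  With acceptance at ``score <=
delta``, sweeping delta yields ``FNR(delta)`` (genuine rejected,
non-increasing) and ``FPR(delta)`` (impostors accepted, non-decreasing); the
equal error rate is the value at their crossing, linearly interpolated
between sweep points.  The sweep uses all midpoints of consecutive distinct
observed scores plus {0, 1}, which realizes the exact step-function ROC.

The batch sweep reruns aggregation -> normalization -> decisions for each
batch size ``B`` and reports metrics against the seconds of signal a batch
spans: ``B * W * (1 - overlap) / fs + W * overlap / fs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rstc import BatchedScores, ScoreTensor, batch_min, identify, normalize_scores

__all__ = [
    "ROC",
    "EvalReport",
    "identification_metrics",
    "roc_curve",
    "eer",
    "eer_summary",
    "per_individual_eers",
    "batch_sweep",
    "seconds_per_batch",
]


@dataclass
class ROC:
    thresholds: np.ndarray
    fnr: np.ndarray
    fpr: np.ndarray


@dataclass
class EvalReport:
    confusion: np.ndarray | None = None
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    per_individual_roc: list[ROC] = field(default_factory=list)
    eer_mean: float | None = None
    eer_std: float | None = None
    sweep: dict[int, dict] = field(default_factory=dict)


def identification_metrics(predicted: np.ndarray, truth: np.ndarray, n_classes: int) -> EvalReport:
    """Confusion matrix, accuracy, and macro sensitivity/specificity.

    ``predicted`` and ``truth`` are integer class indices of equal shape.
    """
    predicted = np.asarray(predicted).ravel()
    truth = np.asarray(truth).ravel()
    if predicted.size == 0:
        raise ValueError("no decisions to evaluate")
    if predicted.shape != truth.shape:
        raise ValueError("prediction/truth shape mismatch")
    conf = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(conf, (truth, predicted), 1)
    total = conf.sum()
    acc = float(np.trace(conf)) / total
    sens, spec = [], []
    for c in range(n_classes):
        tp = conf[c, c]
        fn = conf[c].sum() - tp
        fp = conf[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens.append(tp / (tp + fn) if tp + fn else np.nan)
        spec.append(tn / (tn + fp) if tn + fp else np.nan)
    return EvalReport(
        confusion=conf,
        accuracy=acc,
        sensitivity=float(np.nanmean(sens)),
        specificity=float(np.nanmean(spec)),
    )


def _default_thresholds(genuine: np.ndarray, impostor: np.ndarray) -> np.ndarray:
    scores = np.unique(np.concatenate([genuine, impostor]))
    mids = (scores[:-1] + scores[1:]) / 2 if scores.size > 1 else np.array([])
    return np.unique(np.concatenate([[0.0], scores, mids, [1.0]]))


def roc_curve(
    genuine: np.ndarray, impostor: np.ndarray, thresholds: np.ndarray | None = None
) -> ROC:
    """FNR/FPR as functions of the acceptance threshold delta.

    ``FNR(delta)`` = fraction of genuine scores > delta (rejected);
    ``FPR(delta)`` = fraction of impostor scores <= delta (accepted).
    """
    genuine = np.asarray(genuine, dtype=float).ravel()
    impostor = np.asarray(impostor, dtype=float).ravel()
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("need at least one genuine and one impostor score")
    if thresholds is None:
        thresholds = _default_thresholds(genuine, impostor)
    thresholds = np.asarray(thresholds, dtype=float)
    fnr = (genuine[None, :] > thresholds[:, None]).mean(axis=1)
    fpr = (impostor[None, :] <= thresholds[:, None]).mean(axis=1)
    return ROC(thresholds=thresholds, fnr=fnr, fpr=fpr)


def eer(roc: ROC, interpolate: bool = True) -> float:
    """Equal error rate: the value where FNR and FPR cross.

    With interpolation, FNR and FPR are treated as piecewise-linear in delta
    between sweep points and the exact crossing solved; without, the sweep
    point minimizing |FNR - FPR| is taken and (FNR + FPR) / 2 returned.
    """
    d = roc.fnr - roc.fpr  # non-increasing in delta
    if not interpolate:
        k = int(np.argmin(np.abs(d)))
        return float((roc.fnr[k] + roc.fpr[k]) / 2)
    cross = np.nonzero(d <= 0)[0]
    if cross.size == 0:  # never crosses within the sweep
        return float((roc.fnr[-1] + roc.fpr[-1]) / 2)
    k = int(cross[0])
    if d[k] == 0 or k == 0:
        return float(roc.fnr[k])
    d0, d1 = d[k - 1], d[k]
    t = d0 / (d0 - d1)
    return float(roc.fnr[k - 1] + t * (roc.fnr[k] - roc.fnr[k - 1]))


def eer_summary(eers: np.ndarray) -> tuple[float, float]:
    """Mean and population standard deviation of per-individual EERs."""
    eers = np.asarray(eers, dtype=float)
    if eers.size == 0:
        raise ValueError("need at least one individual")
    return float(eers.mean()), float(eers.std())


def per_individual_eers(S_norm: BatchedScores) -> tuple[np.ndarray, list[ROC]]:
    """One ROC/EER per enrolled individual from a normalized score block."""
    P = S_norm.values.shape[0]
    rocs, eers = [], []
    for p in range(P):
        genuine = S_norm.values[p, p, :]
        impostor = np.concatenate(
            [S_norm.values[p, i, :] for i in range(S_norm.values.shape[1]) if i != p]
        )
        r = roc_curve(genuine, impostor)
        rocs.append(r)
        eers.append(eer(r))
    return np.asarray(eers), rocs


def seconds_per_batch(B: int, fs: float, W: int, overlap: float) -> float:
    """Signal seconds spanned by one batch of B overlapped windows."""
    return B * W * (1 - overlap) / fs + W * overlap / fs


def evaluate_at_batch(S: ScoreTensor, B: int) -> EvalReport:
    """Full identification + authentication evaluation at one batch size."""
    S_norm = normalize_scores(batch_min(S, B))
    pred = identify(S_norm)  # (I, n_batches) predictor indices
    I = len(S.subject_ids)
    # truth: subject i's batches belong to the predictor with the same id
    truth_idx = np.array([S.predictor_ids.index(s) for s in S.subject_ids])
    truth = np.repeat(truth_idx[:, None], pred.shape[1], axis=1)
    rep = identification_metrics(pred, truth, n_classes=len(S.predictor_ids))
    eers, rocs = per_individual_eers(S_norm)
    rep.per_individual_roc = rocs
    rep.eer_mean, rep.eer_std = eer_summary(eers)
    return rep


def batch_sweep(
    S: ScoreTensor, B_values: list[int], fs: float, W: int, overlap: float
) -> EvalReport:
    """Evaluate identification and authentication across batch sizes."""
    report = EvalReport()
    for B in B_values:
        rep = evaluate_at_batch(S, B)
        report.sweep[B] = {
            "seconds": seconds_per_batch(B, fs, W, overlap),
            "accuracy": rep.accuracy,
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "eer_mean": rep.eer_mean,
            "eer_std": rep.eer_std,
            "confusion": rep.confusion,
        }
    best = max(B_values)
    final = report.sweep[best]
    report.confusion = final["confusion"]
    report.accuracy = final["accuracy"]
    report.sensitivity = final["sensitivity"]
    report.specificity = final["specificity"]
    report.eer_mean = final["eer_mean"]
    report.eer_std = final["eer_std"]
    return report
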