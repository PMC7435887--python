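"""ECG conditioning: detrending, smoothing, normalization, quantization,
windowing, noisy-window rejection, and R-peak/cycle extraction.

The chain applied to every record before modelling is

    moving-average removal -> Hanning smoothing -> moving absolute-max
    normalization [-> histogram-edge clipping -> quantization]

where the bracketed steps are used only for the integer-sequence path (the
recurrent next-sample predictor needs a discrete amplitude alphabet of ``SD``
levels); the convolutional path consumes the real-valued normalized signal.
The moving-average subtraction removes baseline wander, the unit-sum Hanning
kernel suppresses high-frequency noise, and the moving absolute-maximum
division bounds the signal to [-1, 1] with local gain control.  Clipping is
winsorization at symmetric histogram quantiles (default 0.5% confidence) so
isolated artifacts cannot consume quantization levels.

Quantization maps amplitudes onto ``{0..SD-1}`` by min-max scaling and
rounding (half away from zero, so results do not depend on the platform's
banker's rounding), with the signal minimum at level 0 and maximum at SD-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import butter, filtfilt, find_peaks

from .io import RawRecord

__all__ = [
    "PreprocessConfig",
    "QuantizedWindowSet",
    "remove_moving_average",
    "smooth_hanning",
    "normalize_moving_absmax",
    "clip_histogram_edges",
    "quantize",
    "segment_windows",
    "reject_noisy_windows",
    "detect_r_peaks",
    "extract_cycle",
    "preprocess_signal",
    "build_windows",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """All conditioning parameters, in samples unless noted.

    Window-length defaults assume 250 Hz: 1 s moving average (baseline
    wander), 25 ms Hanning (smoothing), 3 s absolute-max (local gain),
    0.7 s extracted cycle.  Use :meth:`for_fs` for other rates.
    """

    ma_window: int = 251
    hann_window: int = 7
    absmax_window: int = 751
    clip_confidence: float = 0.005
    sd: int = 512  # quantization levels
    window: int = 512  # W, segmentation window
    overlap: float = 0.67
    reject_std_z: float = 3.0
    cycle_len: int = 175

    def __post_init__(self) -> None:
        if not 0 <= self.clip_confidence < 0.5:
            raise ValueError("clip_confidence must lie in [0, 0.5)")
        if self.sd < 2:
            raise ValueError("need at least 2 quantization levels")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")
        if self.window < 2:
            raise ValueError("window must be >= 2 samples")

    @classmethod
    def for_fs(cls, fs: float, **overrides) -> "PreprocessConfig":
        """Defaults expressed in seconds, converted to (odd) sample counts."""

        def odd(x: float) -> int:
            k = max(1, int(round(x)))
            return k if k % 2 == 1 else k + 1

        base = dict(
            ma_window=odd(1.0 * fs),
            hann_window=max(3, odd(0.025 * fs)),
            absmax_window=odd(3.0 * fs),
            cycle_len=int(round(0.7 * fs)),
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class QuantizedWindowSet:
    """Fixed-length overlapped windows with their provenance.

    ``windows`` is ``(n, W)``; integer-valued in ``{0..sd-1}`` for the
    quantized path (``sd`` set), real-valued in [-1, 1] otherwise.  ``starts``
    and ``record_ids`` give each window's half-open source span
    ``[start, start+W)`` inside its record; ``record_lengths`` maps record id
    to total sample count so fractional splits can be reconstructed.
    """

    windows: np.ndarray
    labels: np.ndarray  # subject id per window
    starts: np.ndarray
    record_ids: np.ndarray
    fs: float
    sessions: np.ndarray | None = None
    sd: int | None = None
    record_lengths: dict[str, int] = field(default_factory=dict)
    cycles: np.ndarray | None = None  # (n, cycle_len) R-centered sub-segments
    has_cycle: np.ndarray | None = None  # bool per window

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows)
        if self.windows.ndim != 2:
            raise ValueError("windows must be a (n, W) array")
        n = len(self.windows)
        self.labels = np.asarray(self.labels)
        self.starts = np.asarray(self.starts, dtype=int)
        self.record_ids = np.asarray(self.record_ids)
        if self.sessions is None:
            self.sessions = np.array([""] * n)
        if not (len(self.labels) == len(self.starts) == len(self.record_ids) == n):
            raise ValueError("inconsistent window metadata lengths")
        if self.sd is not None:
            if self.windows.min(initial=0) < 0 or self.windows.max(initial=0) > self.sd - 1:
                raise ValueError("quantized windows must lie in {0..SD-1}")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def window_len(self) -> int:
        return self.windows.shape[1]

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def select(self, mask: np.ndarray) -> "QuantizedWindowSet":
        mask = np.asarray(mask)
        return QuantizedWindowSet(
            windows=self.windows[mask],
            labels=self.labels[mask],
            starts=self.starts[mask],
            record_ids=self.record_ids[mask],
            fs=self.fs,
            sessions=self.sessions[mask],
            sd=self.sd,
            record_lengths=dict(self.record_lengths),
            cycles=None if self.cycles is None else self.cycles[mask],
            has_cycle=None if self.has_cycle is None else self.has_cycle[mask],
        )

    def for_subject(self, subject_id: str) -> "QuantizedWindowSet":
        return self.select(self.labels == subject_id)


# ---------------------------------------------------------------- operators


def remove_moving_average(signal: np.ndarray, ma_window: int) -> np.ndarray:
    """Subtract the centered moving mean (edges use shrunken windows)."""
    signal = np.asarray(signal, dtype=float)
    if ma_window < 1 or ma_window % 2 == 0:
        raise ValueError("ma_window must be an odd positive integer")
    if ma_window > signal.size:
        raise ValueError("ma_window exceeds signal length")
    kern = np.ones(ma_window)
    sums = np.convolve(signal, kern, mode="same")
    counts = np.convolve(np.ones_like(signal), kern, mode="same")
    return signal - sums / counts


def smooth_hanning(signal: np.ndarray, hann_window: int) -> np.ndarray:
    """Convolve with a unit-sum Hanning kernel; reflect padding keeps length
    and preserves constants exactly."""
    signal = np.asarray(signal, dtype=float)
    if hann_window < 3:
        raise ValueError("hann_window must be >= 3")
    if hann_window > signal.size:
        raise ValueError("hann_window exceeds signal length")
    kern = np.hanning(hann_window)
    kern = kern / kern.sum()
    lpad, rpad = hann_window // 2, (hann_window - 1) // 2
    padded = np.pad(signal, (lpad, rpad), mode="reflect")
    return np.convolve(padded, kern, mode="valid")


def normalize_moving_absmax(signal: np.ndarray, absmax_window: int) -> np.ndarray:
    """Divide by the centered moving maximum of ``|signal|``; zero-max -> 0."""
    signal = np.asarray(signal, dtype=float)
    if absmax_window < 1:
        raise ValueError("absmax_window must be >= 1")
    env = maximum_filter1d(np.abs(signal), size=absmax_window, mode="constant", cval=0.0)
    out = np.zeros_like(signal)
    np.divide(signal, env, out=out, where=env > 0)
    return out


def clip_histogram_edges(signal: np.ndarray, clip_confidence: float) -> np.ndarray:
    """Winsorize at the symmetric amplitude quantiles."""
    signal = np.asarray(signal, dtype=float)
    if not 0 <= clip_confidence < 0.5:
        raise ValueError("clip_confidence must lie in [0, 0.5)")
    if clip_confidence == 0:
        return signal.copy()
    lo, hi = np.quantile(signal, [clip_confidence, 1 - clip_confidence])
    return np.clip(signal, lo, hi)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantize(signal: np.ndarray, sd: int) -> np.ndarray:
    """Min-max map onto ``{0..sd-1}``: ``round((s - min) / (max - min) * (sd-1))``."""
    signal = np.asarray(signal, dtype=float)
    if sd < 2:
        raise ValueError("sd must be >= 2")
    lo, hi = signal.min(), signal.max()
    if hi == lo:
        raise ValueError("cannot quantize a constant signal (max == min)")
    x = _round_half_away((signal - lo) / (hi - lo) * (sd - 1)).astype(np.int64)
    return x


def segment_windows(
    signal: np.ndarray,
    window: int,
    overlap: float,
    *,
    fs: float = 250.0,
    subject_id: str = "S0",
    session_id: str = "",
    record_id: str | None = None,
    sd: int | None = None,
) -> QuantizedWindowSet:
    """Cut a signal into overlapped windows of ``window`` samples.

    Step is ``max(1, round(window * (1 - overlap)))``; starts run
    0, step, 2*step, ... while the window fits.
    """
    signal = np.asarray(signal)
    if signal.size < window:
        raise ValueError("signal shorter than one window")
    step = max(1, int(round(window * (1 - overlap))))
    starts = np.arange(0, signal.size - window + 1, step)
    wins = np.stack([signal[s : s + window] for s in starts])
    rid = record_id if record_id is not None else f"{subject_id}:{session_id}"
    n = len(starts)
    return QuantizedWindowSet(
        windows=wins,
        labels=np.array([subject_id] * n),
        starts=starts,
        record_ids=np.array([rid] * n),
        sessions=np.array([session_id] * n),
        fs=fs,
        sd=sd,
        record_lengths={rid: int(signal.size)},
    )


def reject_noisy_windows(
    wset: QuantizedWindowSet, reject_std_z: float = 3.0
) -> tuple[QuantizedWindowSet, float]:
    """Drop windows whose amplitude spread is anomalous for their subject.

    Heavily corrupted windows stand out through their sample standard
    deviation; per subject, a robust z-score (median/MAD) of window stds is
    computed and windows beyond ``reject_std_z`` are removed.  The scale is
    floored at 15% of the median std: when clean windows cluster very
    tightly the MAD goes degenerate and ordinary beat-count variation (one
    vs. two beats inside a window) would otherwise be flagged.  Returns the
    surviving subset and the rejection fraction.
    """
    if reject_std_z <= 0:
        raise ValueError("reject_std_z must be positive")
    stds = wset.windows.astype(float).std(axis=1)
    keep = np.ones(len(wset), dtype=bool)
    for subj in wset.subjects:
        m = wset.labels == subj
        if m.sum() < 2:
            continue
        s = stds[m]
        med = np.median(s)
        mad = np.median(np.abs(s - med))
        scale = max(1.4826 * mad, 0.15 * med)
        if scale == 0:
            continue  # all windows alike: nothing to reject
        keep[m] = np.abs(s - med) / scale <= reject_std_z
    frac = 1.0 - keep.sum() / len(wset)
    return wset.select(keep), float(frac)


def detect_r_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """R-wave locations via derivative -> square -> integrate peak detection.

    Band-passes 5-20 Hz to isolate QRS energy, differentiates, squares, and
    integrates over 150 ms; candidate peaks of the energy envelope (minimum
    spacing 0.3 s, height above 20% of its robust maximum) are refined to the
    local maximum of the band-passed signal.  Returns sorted indices spaced
    at least ``0.3 * fs`` apart; empty for flat signals.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < int(0.5 * fs) or np.ptp(signal) == 0:
        return np.array([], dtype=int)
    nyq = fs / 2
    b, a = butter(2, [min(5 / nyq, 0.9), min(20 / nyq, 0.95)], btype="band")
    bp = filtfilt(b, a, signal)
    energy = np.gradient(bp) ** 2
    win = max(1, int(round(0.15 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    height = 0.2 * np.percentile(integ, 99.5)
    if height <= 0:
        return np.array([], dtype=int)
    cand, _ = find_peaks(integ, distance=int(0.3 * fs), height=height)
    half = int(round(0.1 * fs))
    peaks = []
    for c in cand:
        i0, i1 = max(0, c - half), min(signal.size, c + half + 1)
        peaks.append(i0 + int(np.argmax(bp[i0:i1])))
    peaks = np.unique(peaks)
    # re-enforce spacing after refinement (keep the earlier peak on conflict)
    out: list[int] = []
    for p in peaks:
        if not out or p - out[-1] >= int(0.3 * fs):
            out.append(int(p))
    return np.asarray(out, dtype=int)


def extract_cycle(window: np.ndarray, r_peak: int, cycle_len: int) -> np.ndarray:
    """Crop ``cycle_len`` samples centered on ``r_peak``, zero-padded at edges."""
    window = np.asarray(window, dtype=float)
    if not 0 <= r_peak < window.size:
        raise ValueError("r_peak must lie inside the window")
    half = cycle_len // 2
    out = np.zeros(cycle_len, dtype=float)
    src0 = r_peak - half
    for j in range(cycle_len):
        i = src0 + j
        if 0 <= i < window.size:
            out[j] = window[i]
    return out


# ------------------------------------------------------------------ chains


def preprocess_signal(
    samples: np.ndarray,
    cfg: PreprocessConfig,
    path: Literal["rnn", "tcnn"] = "rnn",
) -> np.ndarray:
    """Run the conditioning chain on a whole record.

    The quantized ("rnn") path appends clipping + quantization; the real
    ("tcnn") path stops after absolute-max normalization.
    """
    x = remove_moving_average(samples, cfg.ma_window)
    x = smooth_hanning(x, cfg.hann_window)
    x = normalize_moving_absmax(x, cfg.absmax_window)
    if path == "rnn":
        x = clip_histogram_edges(x, cfg.clip_confidence)
        x = quantize(x, cfg.sd)
    return x


def _attach_cycles(
    wset: QuantizedWindowSet,
    cfg: PreprocessConfig,
    record_peaks: dict[str, np.ndarray] | None = None,
) -> QuantizedWindowSet:
    """Attach the first R-centered cycle of each window.

    R peaks are located on each whole record (full context makes detection
    far more reliable than per-window runs) and mapped into window
    coordinates; windows containing no peak are flagged for exclusion from
    the fiducial stream.
    """
    n = len(wset)
    W = wset.window_len
    cycles = np.zeros((n, cfg.cycle_len))
    has = np.zeros(n, dtype=bool)
    for k in range(n):
        rid = wset.record_ids[k]
        start = wset.starts[k]
        if record_peaks is not None and rid in record_peaks:
            inside = record_peaks[rid]
            inside = inside[(inside >= start) & (inside < start + W)] - start
        else:
            inside = detect_r_peaks(wset.windows[k], wset.fs)
        if inside.size:
            cycles[k] = extract_cycle(wset.windows[k], int(inside[0]), cfg.cycle_len)
            has[k] = True
    wset.cycles = cycles
    wset.has_cycle = has
    return wset


def build_windows(
    records: list[RawRecord],
    cfg: PreprocessConfig,
    path: Literal["rnn", "tcnn"] = "rnn",
    reject: bool = True,
    with_cycles: bool | None = None,
) -> QuantizedWindowSet:
    """Condition, segment, and pool windows from many records.

    For the convolutional path each window also gets its R-centered cycle
    sub-segment (first detected R peak in the window; windows with no peak
    are flagged so the fiducial stream can skip them).
    """
    if not records:
        raise ValueError("no records given")
    parts = []
    record_peaks: dict[str, np.ndarray] = {}
    for rec in records:
        sig = preprocess_signal(rec.samples, cfg, path=path)
        part = segment_windows(
            sig,
            cfg.window,
            cfg.overlap,
            fs=rec.fs,
            subject_id=rec.subject_id,
            session_id=rec.session_id or "",
            sd=cfg.sd if path == "rnn" else None,
        )
        parts.append(part)
        if path == "tcnn" and with_cycles is not False:
            record_peaks[part.record_ids[0]] = detect_r_peaks(sig, rec.fs)
    wset = _concat(parts)
    if reject:
        wset, _ = reject_noisy_windows(wset, cfg.reject_std_z)
    if with_cycles is None:
        with_cycles = path == "tcnn"
    if with_cycles:
        wset = _attach_cycles(wset, cfg, record_peaks or None)
    return wset


def _concat(parts: list[QuantizedWindowSet]) -> QuantizedWindowSet:
    lengths: dict[str, int] = {}
    for p in parts:
        lengths.update(p.record_lengths)
    return QuantizedWindowSet(
        windows=np.concatenate([p.windows for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        starts=np.concatenate([p.starts for p in parts]),
        record_ids=np.concatenate([p.record_ids for p in parts]),
        sessions=np.concatenate([p.sessions for p in parts]),
        fs=parts[0].fs,
        sd=parts[0].sd,
        record_lengths=lengths,
    )
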