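"""Record I/O, train/test splitting, and score-tensor serialization.

Signals travel as :class:`RawRecord`: a single-channel amplitude series with
its sampling rate and subject/session labels.  Two on-disk formats are read:

* plain CSV, one sample per row (header row optional), sampling rate supplied
  by the caller or a sidecar;
* PhysioNet-style record pairs (``name.hea`` + ``name.dat``) in the two
  common signal formats (16: little-endian int16; 212: packed 12-bit pairs),
  with ADC gain and baseline applied to recover physical units.

Splitting follows the enrolment protocols used for continuous-recording
cohorts: either the first fraction of each record is the training segment
(windows straddling the boundary are dropped so train and test never share a
sample), or, for two-session acquisitions, one whole session trains and the
other tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Literal

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .preprocess import QuantizedWindowSet
    from .rstc import ScoreTensor

__all__ = [
    "RawRecord",
    "SplitSpec",
    "read_record",
    "write_record",
    "split_train_test",
    "save_scores",
    "load_scores",
]


@dataclass(frozen=True)
class RawRecord:
    """One subject's single-channel ECG."""

    subject_id: str
    fs: float
    samples: np.ndarray
    session_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")


@dataclass(frozen=True)
class SplitSpec:
    """How to carve enrolment (train) and probe (test) windows from records."""

    mode: Literal["fraction", "cross-session"] = "fraction"
    train_fraction: float = 0.33
    train_session: str | None = None
    test_session: str | None = None

    def __post_init__(self) -> None:
        if self.mode == "fraction" and not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.mode == "cross-session" and (
            self.train_session is None or self.test_session is None
        ):
            raise ValueError("cross-session mode needs train_session and test_session")


def _read_csv(path: Path, fs: float | None, subject_id: str, session_id: str | None) -> RawRecord:
    if fs is None or fs <= 0:
        raise ValueError("CSV records carry no sampling rate; pass fs > 0")
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty record file")
    start = 0
    try:
        float(lines[0].split(",")[0])
    except ValueError:
        start = 1  # header row
    vals = np.array([float(ln.split(",")[0]) for ln in lines[start:]])
    if vals.size == 0:
        raise ValueError(f"{path}: no samples")
    return RawRecord(subject_id=subject_id, session_id=session_id, fs=fs, samples=vals)


def _decode_dat(raw: bytes, fmt: int, n_samples: int | None) -> np.ndarray:
    if fmt == 16:
        dig = np.frombuffer(raw, dtype="<i2").astype(int)
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8).astype(int)
        usable = (len(b) // 3) * 3
        b = b[:usable].reshape(-1, 3)
        first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        # 12-bit two's complement
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        dig = np.stack([first, second], axis=1).ravel()
    else:
        raise ValueError(f"unsupported PhysioNet signal format {fmt}")
    if n_samples is not None:
        dig = dig[:n_samples]
    return dig


def _read_physionet(path: Path, subject_id: str | None, session_id: str | None) -> RawRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_name, nsig, *rest = lines[0].split()
    nsig = int(nsig)
    fs = float(rest[0]) if rest else 250.0
    n_samples = int(rest[1]) if len(rest) > 1 else None
    if fs <= 0:
        raise ValueError(f"{hea}: non-positive sampling rate in header")
    if nsig != 1:
        raise ValueError(f"{hea}: only single-signal records are supported (nsig={nsig})")

    tok = lines[1].split()
    dat_name, fmt_spec, gain_spec = tok[0], tok[1], tok[2] if len(tok) > 2 else "200"
    fmt = int(fmt_spec.split("x")[0].split(":")[0].split("+")[0])
    gain_part = gain_spec.split("/")[0]
    if "(" in gain_part:
        gain = float(gain_part[: gain_part.index("(")])
        baseline = int(gain_part[gain_part.index("(") + 1 : gain_part.index(")")])
    else:
        gain = float(gain_part)
        baseline = int(tok[4]) if len(tok) > 4 else 0  # ADC zero fallback
    if gain == 0:
        gain = 200.0  # WFDB convention: 0 means "unspecified", default 200 adu/mV

    dig = _decode_dat((hea.parent / dat_name).read_bytes(), fmt, n_samples)
    phys = (dig - baseline) / gain
    return RawRecord(
        subject_id=subject_id or rec_name, session_id=session_id, fs=fs, samples=phys
    )


def read_record(
    path: str | Path,
    format: Literal["csv", "physionet-record"] = "csv",
    fs: float | None = None,
    subject_id: str | None = None,
    session_id: str | None = None,
) -> RawRecord:
    """Read one single-channel record from disk.

    ``fs`` is required for CSV (the format carries none); for PhysioNet
    records the header supplies rate, length, gain, and baseline.
    """
    path = Path(path)
    if not (path.exists() or path.with_suffix(".hea").exists()):
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path, fs, subject_id or path.stem, session_id)
    if format == "physionet-record":
        return _read_physionet(path, subject_id, session_id)
    raise ValueError(f"unknown record format {format!r}")


def write_record(rec: RawRecord, path: str | Path, header: bool = False) -> None:
    """Write a record as one-sample-per-row CSV at full precision."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("amplitude\n")
        for v in rec.samples:
            fh.write(f"{float(v)!r}\n")


def split_train_test(
    windows: "QuantizedWindowSet", spec: SplitSpec
) -> tuple["QuantizedWindowSet", "QuantizedWindowSet"]:
    """Split a window set into disjoint enrolment and probe subsets.

    Fraction mode: for each source record of length ``n`` the boundary sits at
    ``floor(train_fraction * n)``; a window trains iff it lies entirely before
    the boundary and tests iff entirely at/after it.  Straddling windows are
    dropped, so the two sets never share a sample index.  Cross-session mode
    assigns whole sessions.
    """
    W = windows.window_len
    if spec.mode == "fraction":
        train_mask = np.zeros(len(windows), dtype=bool)
        test_mask = np.zeros(len(windows), dtype=bool)
        for k in range(len(windows)):
            rid = windows.record_ids[k]
            boundary = int(np.floor(spec.train_fraction * windows.record_lengths[rid]))
            s = windows.starts[k]
            if s + W <= boundary:
                train_mask[k] = True
            elif s >= boundary:
                test_mask[k] = True
    else:
        sessions = np.asarray(windows.sessions)
        train_mask = sessions == spec.train_session
        test_mask = sessions == spec.test_session
        if not train_mask.any() or not test_mask.any():
            raise ValueError(
                "cross-session split needs windows from both "
                f"{spec.train_session!r} and {spec.test_session!r}"
            )
    return windows.select(train_mask), windows.select(test_mask)


def save_windows(wset: "QuantizedWindowSet", path: str | Path) -> None:
    """Serialize a window set (arrays + labels + spans) as an ``.npz`` archive."""
    payload = dict(
        windows=wset.windows,
        labels=wset.labels,
        starts=wset.starts,
        record_ids=wset.record_ids,
        sessions=wset.sessions,
        fs=np.array(wset.fs),
        sd=np.array(-1 if wset.sd is None else wset.sd),
        record_lengths=np.array(json.dumps(wset.record_lengths)),
    )
    if wset.cycles is not None:
        payload["cycles"] = wset.cycles
        payload["has_cycle"] = wset.has_cycle
    np.savez(Path(path), **payload)


def load_windows(path: str | Path) -> "QuantizedWindowSet":
    from .preprocess import QuantizedWindowSet

    z = np.load(Path(path), allow_pickle=False)
    sd = int(z["sd"])
    return QuantizedWindowSet(
        windows=z["windows"],
        labels=z["labels"],
        starts=z["starts"],
        record_ids=z["record_ids"],
        sessions=z["sessions"],
        fs=float(z["fs"]),
        sd=None if sd < 0 else sd,
        record_lengths=json.loads(str(z["record_lengths"])),
        cycles=z["cycles"] if "cycles" in z else None,
        has_cycle=z["has_cycle"] if "has_cycle" in z else None,
    )


def save_scores(scores: "ScoreTensor", path: str | Path) -> None:
    """Serialize a score tensor as a dense ``.npy`` plus a JSON index sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), scores.values)
    sidecar = {
        "predictor_ids": list(scores.predictor_ids),
        "subject_ids": list(scores.subject_ids),
        "window_ids": [int(w) for w in scores.window_ids],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_scores(path: str | Path) -> "ScoreTensor":
    from .rstc import ScoreTensor

    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return ScoreTensor(
        values=values,
        predictor_ids=meta["predictor_ids"],
        subject_ids=meta["subject_ids"],
        window_ids=np.asarray(meta["window_ids"]),
    )
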