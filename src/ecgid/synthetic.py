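"""Synthetic multi-subject ECG cohorts with ground-truth beat locations.

Each subject is a bundle of PQRST wave parameters (a Gaussian bump per wave),
a mean RR interval with beat-to-beat jitter, sinusoidal baseline wander, and
additive white noise.  A cohort draws per-subject parameters from uniform
ranges whose dispersion around the range midpoint is scaled by ``separation``,
so ``separation=0`` collapses every subject onto the same template and larger
values spread the cohort apart.  A second acquisition session can be simulated
by perturbing every morphology parameter multiplicatively (``session_drift``),
emulating the electrode-placement and physiological changes seen between
recordings taken months apart.

The Gaussian-bump beat model is chosen over dynamical-system ECG simulators
because it gives analytic ground truth (exact R locations, exact per-wave
amplitudes) and is fast enough to regenerate cohorts inside the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import RawRecord

__all__ = [
    "WaveParams",
    "SubjectMorphology",
    "CohortSpec",
    "sample_morphology",
    "synthesize_record",
    "make_cohort",
]

#: wave name -> (amplitude range, center-offset range [s rel. R], width range [s])
_WAVE_RANGES: dict[str, tuple[tuple[float, float], tuple[float, float], tuple[float, float]]] = {
    "P": ((0.08, 0.20), (-0.26, -0.18), (0.020, 0.035)),
    "Q": ((-0.20, -0.05), (-0.050, -0.030), (0.008, 0.015)),
    "R": ((0.90, 1.40), (-0.002, 0.002), (0.010, 0.018)),
    "S": ((-0.35, -0.10), (0.025, 0.045), (0.008, 0.015)),
    "T": ((0.20, 0.45), (0.25, 0.35), (0.040, 0.070)),
}

_RR_RANGE = (0.70, 1.10)  # s; resting adult heart rates ~55-85 bpm


@dataclass(frozen=True)
class WaveParams:
    """One ECG wave as a Gaussian bump: ``amp * exp(-(t - center)^2 / 2 width^2)``."""

    amplitude: float
    center: float  # s, relative to the R peak
    width: float  # s, Gaussian sigma


@dataclass(frozen=True)
class SubjectMorphology:
    """Full parameter set describing one subject's beat shape and rhythm."""

    waves: dict[str, WaveParams]
    mean_rr: float  # s
    rr_jitter_std: float = 0.03  # s
    wander_amplitude: float = 0.10  # a.u.
    wander_freq: float = 0.25  # Hz
    noise_std: float = 0.03  # a.u.

    def __post_init__(self) -> None:
        if not 0.4 <= self.mean_rr <= 1.5:
            raise ValueError(f"mean RR {self.mean_rr} s outside physiological [0.4, 1.5] s")
        for name, w in self.waves.items():
            if w.width <= 0:
                raise ValueError(f"wave {name} has non-positive width")
        r_amp = abs(self.waves["R"].amplitude)
        for name, w in self.waves.items():
            if name != "R" and abs(w.amplitude) >= r_amp:
                raise ValueError("R wave must dominate all other wave amplitudes")


@dataclass(frozen=True)
class CohortSpec:
    """Study design for a synthetic cohort.

    ``separation`` scales how far apart subjects sit in parameter space;
    ``session_drift`` is the fractional multiplicative morphology perturbation
    applied between session 1 and session 2.
    """

    n_subjects: int = 5
    duration: float = 240.0  # s per subject per session
    fs: float = 250.0  # Hz
    separation: float = 1.0
    session_drift: float = 0.0
    n_sessions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")


def _subject_rng(spec: CohortSpec, subject: int, stream: int) -> np.random.Generator:
    # counter-based: every (seed, subject, stream) triple is reproducible in isolation
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(subject, stream))
    return np.random.default_rng(ss)


def sample_morphology(spec: CohortSpec, subject: int) -> SubjectMorphology:
    """Draw subject ``subject``'s morphology, deterministically in (seed, subject).

    The mean RR interval is stratified across the cohort (subject ``j`` sits at
    the ``(j + 0.5)/n`` quantile of the RR range before jitter), which
    guarantees any two subjects differ in at least one parameter by at least
    ``separation * range / 4`` for cohorts of up to ~5 subjects; the remaining
    wave parameters are drawn uniformly.  All dispersion is scaled by
    ``separation`` around each range midpoint.
    """
    rng = _subject_rng(spec, subject, stream=0)
    sep = spec.separation

    def scaled(lo: float, hi: float, value: float) -> float:
        mid = 0.5 * (lo + hi)
        return mid + sep * (value - mid)

    waves = {}
    for name, (a_rng, c_rng, w_rng) in _WAVE_RANGES.items():
        amp = scaled(*a_rng, rng.uniform(*a_rng))
        cen = scaled(*c_rng, rng.uniform(*c_rng))
        wid = scaled(*w_rng, rng.uniform(*w_rng))
        waves[name] = WaveParams(amplitude=amp, center=cen, width=wid)

    lo, hi = _RR_RANGE
    base = lo + (subject % spec.n_subjects + 0.5) / spec.n_subjects * (hi - lo)
    jitter = rng.uniform(-0.25, 0.25) * (hi - lo) / spec.n_subjects
    mean_rr = scaled(lo, hi, base + jitter)
    return SubjectMorphology(waves=waves, mean_rr=mean_rr)


def drift_morphology(
    m: SubjectMorphology, drift: float, rng: np.random.Generator
) -> SubjectMorphology:
    """Perturb every wave parameter multiplicatively by ``1 + drift * U(-1, 1)``."""
    if drift == 0:
        return m
    waves = {}
    for name, w in m.waves.items():
        f = 1.0 + drift * rng.uniform(-1, 1, size=3)
        waves[name] = WaveParams(
            amplitude=w.amplitude * f[0],
            # shifting the R center would redefine the beat time, keep it pinned
            center=w.center * f[1] if name != "R" else w.center,
            width=w.width * f[2],
        )
    rr = float(np.clip(m.mean_rr * (1.0 + drift * rng.uniform(-1, 1)), 0.4, 1.5))
    return replace(m, waves=waves, mean_rr=rr)


def synthesize_record(
    m: SubjectMorphology,
    duration: float,
    fs: float,
    seed: int | np.random.Generator,
    subject_id: str = "S0",
    session_id: str | None = None,
) -> tuple[RawRecord, np.ndarray]:
    """Render one record; returns the record and the true R-peak sample indices.

    Beat times advance by ``mean_rr + N(0, rr_jitter_std)`` (floored at 0.4 s);
    each beat adds its five Gaussian bumps; baseline wander and white noise are
    superimposed on the whole record.
    """
    if duration < 2 * m.mean_rr:
        raise ValueError("duration must cover at least two beats")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)

    beat_times = []
    tb = float(rng.uniform(0.1, 0.5))  # first beat phase
    while tb < duration:
        beat_times.append(tb)
        tb += max(0.4, m.mean_rr + rng.normal(0.0, m.rr_jitter_std))
    beat_times = np.asarray(beat_times)

    for name, w in m.waves.items():
        centers = beat_times + w.center  # (n_beats,)
        # evaluate each bump only on a +-4 sigma support for speed
        half = max(1, int(np.ceil(4 * w.width * fs)))
        for c in centers:
            i0 = max(0, int(np.floor((c * fs))) - half)
            i1 = min(n, int(np.ceil((c * fs))) + half + 1)
            if i0 >= i1:
                continue
            sig[i0:i1] += w.amplitude * np.exp(-((t[i0:i1] - c) ** 2) / (2 * w.width**2))

    if m.wander_amplitude:
        phase = rng.uniform(0, 2 * np.pi)
        sig += m.wander_amplitude * np.sin(2 * np.pi * m.wander_freq * t + phase)
    if m.noise_std:
        sig += rng.normal(0.0, m.noise_std, size=n)

    r_idx = np.round(beat_times * fs).astype(int)
    r_idx = r_idx[r_idx < n]
    rec = RawRecord(subject_id=subject_id, session_id=session_id, fs=fs, samples=sig)
    return rec, r_idx


@dataclass
class CohortGroundTruth:
    """Per-record truth emitted next to a cohort: morphologies and R indices."""

    morphologies: dict[tuple[str, str], SubjectMorphology] = field(default_factory=dict)
    r_peaks: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def make_cohort(spec: CohortSpec) -> tuple[list[RawRecord], CohortGroundTruth]:
    """Generate ``n_subjects x n_sessions`` records plus their ground truth.

    Session 1 uses each subject's sampled morphology; later sessions use the
    morphology perturbed by ``session_drift``.  Subject ids are ``S00, S01...``
    and session ids ``M1, M2...`` (the two-session naming convention of
    off-person acquisition studies).
    """
    records: list[RawRecord] = []
    truth = CohortGroundTruth()
    for j in range(spec.n_subjects):
        sid = f"S{j:02d}"
        base = sample_morphology(spec, j)
        for s in range(spec.n_sessions):
            session = f"M{s + 1}"
            drift_rng = _subject_rng(spec, j, stream=100 + s)
            m = base if s == 0 else drift_morphology(base, spec.session_drift, drift_rng)
            rec_rng = _subject_rng(spec, j, stream=200 + s)
            rec, r_idx = synthesize_record(
                m, spec.duration, spec.fs, rec_rng, subject_id=sid, session_id=session
            )
            records.append(rec)
            truth.morphologies[(sid, session)] = m
            truth.r_peaks[(sid, session)] = r_idx
    return records, truth
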