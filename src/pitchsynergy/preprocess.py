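"""Raw EMG to envelope tensor: rectification, low-pass, resampling, QC.

The fixed per-trial chain is

1. subtract the per-channel offset (mean over the whole recording),
2. full-wave rectification,
3. zero-phase 10 Hz low-pass (FIR, Kaiser design, >= 60 dB stopband,
   transition width 1% of the Nyquist-to-passband span, applied
   forward-backward so burst timing is not lagged),
4. resample to 200 Hz by decimation (the 10 Hz filter already prevents
   aliasing),
5. keep the 150 frames (750 ms) ending at the ball-release frame.

Min-max normalization maps each muscle's values to [0, 1] jointly over
all frames and trials of a subject, so effort-dependent amplitude
differences between trials survive. The subject-level QC rule flags a
(muscle, trial) pair when the trial's peak envelope exceeds
mean + 3 sd of that muscle's per-trial peaks, flags a muscle with more
than ten extreme trials, and excludes a subject with more than ten
flagged muscles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import signal

from .data import EMGTensor, RawEMGRecording, EFFORT_LEVELS
from .exceptions import (
    AssemblyError,
    DataError,
    DegenerateChannelError,
    WindowError,
)

__all__ = [
    "preprocess_recording",
    "assemble_tensor",
    "minmax_normalize",
    "qc_subject",
    "QCResult",
]


@lru_cache(maxsize=8)
def _lowpass_taps(fs: float, cutoff: float, atten_db: float = 60.0) -> np.ndarray:
    nyq = fs / 2.0
    width = 0.01 * (nyq - cutoff)  # steepness 0.99 contract
    numtaps, beta = signal.kaiserord(atten_db, width / nyq)
    numtaps += 1 - numtaps % 2  # odd length, symmetric
    return signal.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs)


def lowpass_envelope(x: np.ndarray, fs: float, cutoff: float = 10.0) -> np.ndarray:
    """Zero-phase low-pass along axis 0."""
    taps = _lowpass_taps(fs, cutoff)
    padlen = min(3 * (len(taps) - 1), x.shape[0] - 1)
    return signal.filtfilt(taps, 1.0, x, axis=0, padlen=padlen)


def preprocess_recording(
    rec: RawEMGRecording,
    target_fs: float = 200.0,
    window_ms: float = 750.0,
    lowpass_hz: float = 10.0,
) -> np.ndarray:
    """Envelope matrix ``(S, n_frames)`` for one trial.

    ``n_frames = window_ms / 1000 * target_fs`` frames end exactly at the
    release frame (150 at the defaults). Filter ringing below zero is
    clipped at 0.
    """
    x = rec.samples
    if not np.all(np.isfinite(x)):
        raise DataError(f"non-finite samples in trial {rec.trial_id}")
    step = rec.sampling_rate / target_fs
    if abs(step - round(step)) > 1e-9:
        raise DataError(
            f"sampling rate {rec.sampling_rate} is not an integer multiple "
            f"of target rate {target_fs}")
    step = int(round(step))
    n_frames = int(round(window_ms / 1000.0 * target_fs))
    first = rec.release_index - (n_frames - 1) * step
    if first < 0 or rec.release_index >= x.shape[0]:
        raise WindowError(
            f"{window_ms} ms window ending at sample {rec.release_index} "
            f"does not fit a recording of {x.shape[0]} samples")

    x = x - x.mean(axis=0, keepdims=True)
    x = np.abs(x)
    y = lowpass_envelope(x, rec.sampling_rate, lowpass_hz)
    frames = y[first:rec.release_index + 1:step]
    return np.clip(frames.T, 0.0, None)


def assemble_tensor(
    envelopes: list[np.ndarray],
    effort_labels: np.ndarray,
    ball_speeds: np.ndarray | None = None,
    muscle_labels: tuple[str, ...] | None = None,
    subject_id: str = "S1",
    trial_ids: np.ndarray | None = None,
) -> EMGTensor:
    """Stack per-trial envelope matrices into an ``(S, T, K)`` tensor.

    Trials are reordered into canonical effort blocks (50, 80, 100) —
    by ``trial_ids`` within each block when given, else stably by input
    position — so shuffled input with labels yields the same tensor as
    block-ordered input. Values are not modified.
    """
    shapes = {e.shape for e in envelopes}
    if len(shapes) != 1:
        raise AssemblyError(f"envelope shapes differ: {sorted(shapes)}")
    effort_labels = np.asarray(effort_labels, dtype=int)
    if len(envelopes) != effort_labels.size:
        raise AssemblyError("one effort label per envelope is required")
    within = (np.asarray(trial_ids) if trial_ids is not None
              else np.arange(effort_labels.size))
    order = np.concatenate([
        sorted(np.flatnonzero(effort_labels == e), key=lambda i: within[i])
        for e in EFFORT_LEVELS])
    order = np.asarray(order, dtype=int)
    if order.size != effort_labels.size:
        bad = sorted(set(effort_labels) - set(EFFORT_LEVELS))
        raise AssemblyError(f"unknown effort labels {bad}")
    X = np.stack([envelopes[i] for i in order], axis=2)
    S = X.shape[0]
    labels = muscle_labels if muscle_labels is not None else tuple(
        f"M{i + 1}" for i in range(S))
    speeds = None
    if ball_speeds is not None:
        speeds = np.asarray(ball_speeds, dtype=float)[order]
    return EMGTensor(
        X=X, muscle_labels=labels, effort_labels=effort_labels[order],
        ball_speeds=speeds, subject_id=subject_id)


def minmax_normalize(tensor: EMGTensor) -> EMGTensor:
    """Scale each muscle's values to span [0, 1] over all frames and trials.

    Idempotent; a constant muscle slice raises
    :class:`DegenerateChannelError` naming the muscle.
    """
    X = tensor.X
    lo = X.min(axis=(1, 2), keepdims=True)
    hi = X.max(axis=(1, 2), keepdims=True)
    flat = np.flatnonzero((hi - lo).ravel() <= 0)
    if flat.size:
        name = tensor.muscle_labels[flat[0]]
        raise DegenerateChannelError(
            f"muscle {name!r} is constant; min-max normalization undefined")
    return replace(tensor, X=(X - lo) / (hi - lo), normalized=True)


@dataclass
class QCResult:
    """Outcome of the subject-level artifact screen."""

    keep: bool
    flagged_muscles: list[int]
    extreme_pairs: list[tuple[int, int]]
    extreme_counts: np.ndarray  # per-muscle count of extreme trials

    #: thresholds of the screen: a muscle is flagged when its extreme-
    #: trial count exceeds ``max_extreme_trials``; the subject is
    #: excluded when the flagged-muscle count exceeds ``max_flagged``.
    max_extreme_trials: int = 10
    max_flagged_muscles: int = 10


def qc_subject(
    data: EMGTensor | np.ndarray,
    max_extreme_trials: int = 10,
    max_flagged_muscles: int = 10,
) -> QCResult:
    """Screen one subject's trials for extreme per-trial peak envelopes.

    A (muscle, trial) pair is extreme when the trial's peak envelope for
    that muscle exceeds mean + 3 sd of that muscle's per-trial peaks.
    Degenerate sd = 0 counts as no extremes.
    """
    X = data.X if isinstance(data, EMGTensor) else np.asarray(data, dtype=float)
    if X.ndim != 3 or X.shape[2] < 2:
        raise ValueError("need an (S, T, K) array with at least 2 trials")
    peaks = X.max(axis=1)  # (S, K)
    mean = peaks.mean(axis=1, keepdims=True)
    sd = peaks.std(axis=1, ddof=1, keepdims=True)
    extreme = (sd > 0) & (peaks > mean + 3.0 * sd)
    counts = extreme.sum(axis=1)
    flagged = np.flatnonzero(counts > max_extreme_trials)
    pairs = [(int(i), int(k)) for i, k in zip(*np.nonzero(extreme))]
    return QCResult(
        keep=flagged.size <= max_flagged_muscles,
        flagged_muscles=[int(i) for i in flagged],
        extreme_pairs=pairs,
        extreme_counts=counts,
        max_extreme_trials=max_extreme_trials,
        max_flagged_muscles=max_flagged_muscles,
    )
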