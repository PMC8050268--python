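"""Core data containers: raw EMG recordings and the muscles x frames x trials tensor.

The analysis tensor ``X`` has shape ``(S, T, K)`` — S muscle channels,
T time frames at 200 Hz ending at ball release, K trials grouped in
effort blocks (50%, 80%, 100%). Frames are 0-based in memory; the release
frame is the last one. Serialized files use 1-based frame and trial
numbers (see :mod:`pitchsynergy.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConstraintError

#: Canonical channel order: 9 muscles x (dominant, nondominant) side.
#: FCU flexor carpi ulnaris, ECR extensor carpi radialis longus,
#: BB biceps brachii, TB triceps brachii, DL deltoid middle strand,
#: PM pectoralis major, TU upper trapezius, TM middle trapezius,
#: EO external oblique.
CHANNEL_ORDER: tuple[str, ...] = (
    "FCU-D", "FCU-ND", "ECR-D", "ECR-ND", "BB-D", "BB-ND",
    "TB-D", "TB-ND", "DL-D", "DL-ND", "PM-D", "PM-ND",
    "TU-D", "TU-ND", "TM-D", "TM-ND", "EO-D", "EO-ND",
)

#: Effort levels, as percent of subjective maximum, in block order.
EFFORT_LEVELS: tuple[int, ...] = (50, 80, 100)


@dataclass
class RawEMGRecording:
    """One trial of multi-channel surface EMG at the recording rate.

    Parameters
    ----------
    samples
        ``(n_samples, S)`` array in volts (arbitrary gain).
    sampling_rate
        Recording rate in Hz (2000 by default).
    channel_labels
        Ordered ``(muscle, side)`` labels; canonical order is
        :data:`CHANNEL_ORDER`.
    release_index
        Sample index of ball release inside ``samples``.
    effort
        Effort level of this trial: 50, 80 or 100.
    ball_speed
        Measured (or simulated) ball-release speed, km/h.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    release_index: int
    effort: int
    ball_speed: float
    subject_id: str = "S1"
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_samples, n_channels) array")
        if self.effort not in EFFORT_LEVELS:
            raise ValueError(f"effort must be one of {EFFORT_LEVELS}, got {self.effort}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class EMGTensor:
    """Nonnegative 3-way EMG envelope array with trial metadata.

    ``X[i, j, k]`` is the envelope of muscle ``i`` at frame ``j`` in trial
    ``k``. Frame ``j`` corresponds to ``(T - 1 - j) * 5`` ms before ball
    release at the default 200 Hz frame rate; release is the final frame.
    """

    X: np.ndarray
    muscle_labels: tuple[str, ...]
    effort_labels: np.ndarray
    ball_speeds: np.ndarray | None = None
    subject_id: str = "S1"
    frame_rate_hz: float = 200.0
    normalized: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 3:
            raise ValueError("X must have shape (muscles, frames, trials)")
        if np.any(self.X < 0):
            raise ConstraintError("EMG tensor must be nonnegative")
        self.muscle_labels = tuple(self.muscle_labels)
        if len(self.muscle_labels) != self.X.shape[0]:
            raise ValueError("muscle_labels length must match X.shape[0]")
        self.effort_labels = np.asarray(self.effort_labels, dtype=int)
        if self.effort_labels.shape != (self.X.shape[2],):
            raise ValueError("effort_labels length must match X.shape[2]")
        if self.ball_speeds is not None:
            self.ball_speeds = np.asarray(self.ball_speeds, dtype=float)
            if self.ball_speeds.shape != (self.X.shape[2],):
                raise ValueError("ball_speeds length must match X.shape[2]")

    @property
    def n_muscles(self) -> int:
        return self.X.shape[0]

    @property
    def n_frames(self) -> int:
        return self.X.shape[1]

    @property
    def n_trials(self) -> int:
        return self.X.shape[2]

    @property
    def frame_times_ms(self) -> np.ndarray:
        """Time of each frame relative to ball release (release = 0 ms)."""
        step = 1000.0 / self.frame_rate_hz
        return -step * np.arange(self.n_frames - 1, -1, -1)

    def effort_masks(self) -> dict[int, np.ndarray]:
        """Boolean trial mask per effort level present in the tensor."""
        return {int(e): self.effort_labels == e for e in np.unique(self.effort_labels)}
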