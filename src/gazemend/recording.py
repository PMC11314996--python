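"""The in-memory gaze time-series container.

A :class:`GazeRecording` is a uniformly(-ish) sampled monocular gaze trace:
timestamps in milliseconds, screen positions in pixels (origin top-left,
x rightward, y downward) and a validity mask. Missing samples (tracking
loss during blinks, mostly) are represented by ``valid=False`` rather than
sentinel coordinates, because (0, 0) is a legal on-screen position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GazeRecording"]


class RecordingError(ValueError):
    """Raised for malformed gaze recordings."""


@dataclass
class GazeRecording:
    """Sample-level monocular gaze recording.

    Attributes
    ----------
    t : ndarray, float64, milliseconds
        Strictly increasing timestamps.
    x, y : ndarray, float64, pixels
        Gaze position; NaN is permitted only where ``valid`` is False.
    valid : ndarray, bool
        False marks null/lost samples.
    subject_id : str
    sampling_rate_hz : float
        Nominal acquisition rate (default 1000 Hz). Velocities always use
        actual timestamp differences, so a wrong nominal rate is harmless
        to the processing chain.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    subject_id: str = ""
    sampling_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.valid is None:
            self.valid = np.isfinite(self.x) & np.isfinite(self.y)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise RecordingError("t, x, y, valid must have equal lengths")
        if self.sampling_rate_hz <= 0:
            raise RecordingError("sampling_rate_hz must be positive")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise RecordingError("timestamps must be strictly increasing")
        bad = self.valid & ~(np.isfinite(self.x) & np.isfinite(self.y))
        if np.any(bad):
            raise RecordingError(f"{int(bad.sum())} samples are valid=True but have non-finite positions")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_ms(self) -> float:
        """Span from first to last timestamp plus one nominal sample period."""
        if len(self) == 0:
            return 0.0
        return float(self.t[-1] - self.t[0]) + 1000.0 / self.sampling_rate_hz

    @property
    def dt_ms(self) -> float:
        """Nominal sample period in ms."""
        return 1000.0 / self.sampling_rate_hz

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            t=self.t.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            valid=self.valid.copy(),
            subject_id=self.subject_id,
            sampling_rate_hz=self.sampling_rate_hz,
        )

    def equals(self, other: "GazeRecording") -> bool:
        """Field-wise equality; invalid samples compare equal regardless of position."""
        if len(self) != len(other):
            return False
        if not (np.array_equal(self.t, other.t) and np.array_equal(self.valid, other.valid)):
            return False
        m = self.valid
        return bool(np.array_equal(self.x[m], other.x[m]) and np.array_equal(self.y[m], other.y[m]))
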