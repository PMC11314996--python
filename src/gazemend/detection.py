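"""Velocity computation and segmentation of the three artifact classes.

High-rate video eye trackers in the scanner produce three stereotyped
kinds of bad data:

* **transient spikes** -- the reported gaze jumps off the true trajectory
  for a few milliseconds and snaps straight back;
* **spatial displacements** -- the reported gaze shifts to an offset
  position for tens to a few hundred milliseconds while the *relative*
  motion within the episode stays accurate, then returns;
* **blink artifacts** -- runs of null samples while the eye is closed,
  flanked by sharp vertical excursions of the reported gaze for roughly
  0.1 s on each side.

Blinks are found from the validity mask. The two sensor artifacts are
found from per-sample velocity: a sample faster than the physiological
saccade ceiling (0.9 deg/ms, i.e. ~40 px/ms under the default geometry)
cannot be a real eye movement, and because an artifact ends by jumping
*back*, its entry and exit velocities point in opposite directions. A
super-threshold onset is therefore paired with the next super-threshold
event whose velocity has negative dot product with the onset velocity;
the enclosed interval is a spike if short, a displacement otherwise.

All intervals are half-open ``[start_ms, end_ms)``: ``end_ms`` is the
timestamp of the first trusted sample after the artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import GazeRecording

__all__ = [
    "VelocityTrace",
    "ArtifactInterval",
    "DetectorConfig",
    "compute_velocity",
    "detect_blink_intervals",
    "segment_sensor_artifacts",
    "intervals_to_tsv",
]

SPIKE = "transient_spike"
DISPLACEMENT = "spatial_displacement"
BLINK = "blink"
KINDS = (SPIKE, DISPLACEMENT, BLINK)


class DetectionError(ValueError):
    """Raised for precondition violations in the detection stage."""


@dataclass
class VelocityTrace:
    """Backward-difference velocity, aligned with the recording's samples.

    ``v[i] = (p[i] - p[i-1]) / (t[i] - t[i-1])`` in px/ms. The first
    sample, and any sample where it or its predecessor is invalid, has
    ``defined=False`` (its vx/vy/speed are NaN).
    """

    t: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    defined: np.ndarray


@dataclass
class ArtifactInterval:
    """A labelled artifact episode, half-open ``[start_ms, end_ms)``."""

    kind: str
    start_ms: float
    end_ms: float
    onset_velocity: tuple[float, float] = (np.nan, np.nan)
    offset_velocity: tuple[float, float] = (np.nan, np.nan)
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise DetectionError(f"unknown artifact kind {self.kind!r}")
        if not self.start_ms < self.end_ms:
            raise DetectionError(f"interval must have start_ms < end_ms, got [{self.start_ms}, {self.end_ms})")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    @property
    def midpoint_ms(self) -> float:
        return 0.5 * (self.start_ms + self.end_ms)


@dataclass
class DetectorConfig:
    """Tunables of the velocity-threshold detector.

    speed_threshold
        px/ms; default 40, the pixel equivalent of the 0.9 deg/ms saccade
        speed ceiling under the default geometry. Use
        :func:`gazemend.geometry.deg_per_ms_to_px_per_ms` to derive it for
        another display.
    max_spike_ms
        Episodes at or below this duration are classified transient_spike.
    max_displacement_ms
        Search horizon for the return jump; an onset with no opposite-
        direction event within it is reported note="unterminated".
    blink_pad_ms
        Margin discarded on each side of a null run during correction
        (covers the ~0.1 s pre/post-blink excursions with headroom).
    """

    speed_threshold: float = 40.0
    max_spike_ms: float = 10.0
    max_displacement_ms: float = 500.0
    blink_pad_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.speed_threshold <= 0:
            raise DetectionError("speed_threshold must be positive")
        if not 0 < self.max_spike_ms < self.max_displacement_ms:
            raise DetectionError("need 0 < max_spike_ms < max_displacement_ms")
        if self.blink_pad_ms < 0:
            raise DetectionError("blink_pad_ms must be non-negative")


def compute_velocity(rec: GazeRecording) -> VelocityTrace:
    """Per-sample backward-difference velocity in px/ms.

    Uses actual timestamp differences, so irregular sampling is handled;
    a backward (not central) difference keeps each velocity causal, which
    matters when corrections are reintegrated sample by sample.

    Raises
    ------
    DetectionError
        If the recording has fewer than 2 samples.
    """
    n = len(rec)
    if n < 2:
        raise DetectionError("need at least 2 samples to compute velocity")
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    dt = np.diff(rec.t)
    vx[1:] = np.diff(rec.x) / dt
    vy[1:] = np.diff(rec.y) / dt
    defined = np.zeros(n, dtype=bool)
    defined[1:] = rec.valid[1:] & rec.valid[:-1]
    vx[~defined] = np.nan
    vy[~defined] = np.nan
    speed = np.hypot(vx, vy)
    return VelocityTrace(t=rec.t.copy(), vx=vx, vy=vy, speed=speed, defined=defined)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True-runs of ``mask`` as (first_index, last_index) pairs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(np.int8)))
    starts, ends = idx[0::2], idx[1::2] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_blink_intervals(rec: GazeRecording) -> list[ArtifactInterval]:
    """One blink interval per maximal run of null samples.

    The interval covers exactly the invalid samples: ``start_ms`` is the
    first invalid timestamp, ``end_ms`` the timestamp of the next valid
    sample (or last timestamp + one nominal period at the record tail).
    Pre/post padding is applied later, at correction time.
    """
    out: list[ArtifactInterval] = []
    for i0, i1 in _runs(~rec.valid):
        end = rec.t[i1 + 1] if i1 + 1 < len(rec) else rec.t[i1] + rec.dt_ms
        out.append(ArtifactInterval(kind=BLINK, start_ms=float(rec.t[i0]), end_ms=float(end)))
    return out


def segment_sensor_artifacts(vel: VelocityTrace, cfg: DetectorConfig | None = None) -> list[ArtifactInterval]:
    """Segment super-threshold episodes into spikes and displacements.

    Scans velocity samples exceeding ``cfg.speed_threshold``. Each onset
    event is paired with the next super-threshold event whose velocity
    vector has negative dot product with the onset's (the return jump)
    within ``cfg.max_displacement_ms``; events in between are absorbed
    into the episode. The half-open interval runs from the onset sample
    to the return-jump sample (the first trusted sample). Duration at or
    below ``cfg.max_spike_ms`` makes it a transient_spike, else a
    spatial_displacement. Onsets with no qualifying return jump are
    emitted with note="unterminated".

    The input velocity must come from a blink-free recording (correct
    blinks first): undefined samples past the first raise DetectionError.
    """
    cfg = cfg or DetectorConfig()
    if not vel.defined[1:].all():
        raise DetectionError("velocity has undefined samples beyond the first; correct blinks before segmentation")
    events = np.flatnonzero(np.nan_to_num(vel.speed, nan=0.0) > cfg.speed_threshold)
    out: list[ArtifactInterval] = []
    t_last = vel.t[-1]
    k = 0
    while k < len(events):
        i = events[k]
        v_on = np.array([vel.vx[i], vel.vy[i]])
        horizon = vel.t[i] + cfg.max_displacement_ms
        j_match = None
        k2 = k + 1
        while k2 < len(events) and vel.t[events[k2]] <= horizon:
            j = events[k2]
            if vel.vx[j] * v_on[0] + vel.vy[j] * v_on[1] < 0:
                j_match = j
                break
            k2 += 1
        if j_match is None:
            end = min(horizon, t_last + (vel.t[-1] - vel.t[-2]))
            if k + 1 < len(events):  # keep unterminated spans disjoint from later episodes
                end = min(end, vel.t[events[k + 1]])
            end = max(float(end), float(vel.t[i]) + 1e-9)
            out.append(
                ArtifactInterval(
                    kind=DISPLACEMENT,
                    start_ms=float(vel.t[i]),
                    end_ms=end,
                    onset_velocity=(float(vel.vx[i]), float(vel.vy[i])),
                    note="unterminated",
                )
            )
            k += 1
        else:
            duration = float(vel.t[j_match] - vel.t[i])
            kind = SPIKE if duration <= cfg.max_spike_ms else DISPLACEMENT
            out.append(
                ArtifactInterval(
                    kind=kind,
                    start_ms=float(vel.t[i]),
                    end_ms=float(vel.t[j_match]),
                    onset_velocity=(float(vel.vx[i]), float(vel.vy[i])),
                    offset_velocity=(float(vel.vx[j_match]), float(vel.vy[j_match])),
                )
            )
            # consume every event up to and including the return jump
            k = k2 + 1
    return out


def intervals_to_tsv(intervals: list[ArtifactInterval], path) -> None:
    """Serialise a detector report as a BED-like TSV."""
    with open(path, "w") as fh:
        fh.write("start_ms\tend_ms\tkind\tonset_vx\tonset_vy\tnote\n")
        for iv in intervals:
            fh.write(
                f"{iv.start_ms:g}\t{iv.end_ms:g}\t{iv.kind}\t"
                f"{iv.onset_velocity[0]:g}\t{iv.onset_velocity[1]:g}\t{iv.note}\n"
            )
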