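"""Correction schemes for the three artifact classes, and the full
cleaning pass.

Each scheme replaces values in place on an unchanged time base -- the
downstream block/condition bookkeeping needs an unbroken 1000 Hz series,
so corrections never delete or resample:

* **transient spike**: the few bad samples are overwritten with the first
  trusted value after the episode (the value "from the final moment");
  holding the pre-spike value or bridging linearly are offered as
  alternative modes.
* **spatial displacement**: the episode's *relative* motion is trusted
  even though its absolute position is not, so the first derivative of
  the raw positions is reintegrated from the last trusted pre-onset
  position. The corrupted entry jump itself carries unknown true motion;
  it is replaced by one step of the immediately preceding velocity, which
  recovers constant-offset episodes on smooth traces exactly. Raw data
  resume unchanged after the episode (the gaze has returned to the
  correct position).
* **blink**: the null run, widened by ``blink_pad_ms`` on each side to
  swallow the sharp vertical excursions that flank a blink, is refilled
  by per-axis linear interpolation between the nearest trusted samples;
  a gap touching a record boundary is held at the nearest trusted value
  instead of extrapolated.

:func:`clean_recording` runs the whole pipeline: blinks are corrected
*before* velocity-based detection, because the flanking excursions would
otherwise spawn spurious spike detections.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .detection import (
    BLINK,
    DISPLACEMENT,
    SPIKE,
    ArtifactInterval,
    DetectorConfig,
    compute_velocity,
    detect_blink_intervals,
    segment_sensor_artifacts,
)
from .recording import GazeRecording

__all__ = [
    "CleanReport",
    "UncorrectableError",
    "correct_spike",
    "correct_displacement",
    "correct_blink",
    "clean_recording",
    "detect_artifacts",
]


class UncorrectableError(ValueError):
    """Raised when an artifact cannot be corrected (missing anchors)."""


@dataclass
class CleanReport:
    """Audit counts for one cleaning pass."""

    n_spikes: int = 0
    n_displacements: int = 0
    n_blinks: int = 0
    samples_replaced: int = 0
    samples_interpolated: int = 0
    unterminated: int = 0
    config_used: DetectorConfig | None = None

    def all_zero(self) -> bool:
        return (
            self.n_spikes == self.n_displacements == self.n_blinks == 0
            and self.samples_replaced == self.samples_interpolated == self.unterminated == 0
        )

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def _inside(rec: GazeRecording, iv: ArtifactInterval) -> np.ndarray:
    return np.flatnonzero((rec.t >= iv.start_ms) & (rec.t < iv.end_ms))


def correct_spike(rec: GazeRecording, iv: ArtifactInterval, mode: str = "post") -> GazeRecording:
    """Overwrite a transient spike's samples with an anchor value.

    mode="post" (default) uses the first trusted sample at/after the
    interval end, mode="pre" the last trusted sample before the start,
    mode="bridge" the line between those two. All samples outside the
    interval are bit-identical to the input.
    """
    if iv.kind != SPIKE:
        raise UncorrectableError(f"correct_spike expects a transient_spike interval, got {iv.kind}")
    if mode not in ("post", "pre", "bridge"):
        raise UncorrectableError(f"unknown spike correction mode {mode!r}")
    out = rec.copy()
    idx = _inside(rec, iv)
    if idx.size == 0:
        return out
    pre_idx = idx[0] - 1
    post_candidates = np.flatnonzero((rec.t >= iv.end_ms) & rec.valid)
    post_idx = post_candidates[0] if post_candidates.size else None
    has_pre = pre_idx >= 0 and rec.valid[pre_idx]
    if mode == "post" and post_idx is None:
        raise UncorrectableError("spike touches the record end; no post anchor")
    if mode == "pre" and not has_pre:
        raise UncorrectableError("spike touches the record start; no pre anchor")
    if mode == "bridge" and (post_idx is None or not has_pre):
        raise UncorrectableError("spike touches a record boundary; bridge needs both anchors")
    if mode == "post":
        out.x[idx] = rec.x[post_idx]
        out.y[idx] = rec.y[post_idx]
    elif mode == "pre":
        out.x[idx] = rec.x[pre_idx]
        out.y[idx] = rec.y[pre_idx]
    else:
        tp = [rec.t[pre_idx], rec.t[post_idx]]
        out.x[idx] = np.interp(rec.t[idx], tp, [rec.x[pre_idx], rec.x[post_idx]])
        out.y[idx] = np.interp(rec.t[idx], tp, [rec.y[pre_idx], rec.y[post_idx]])
    out.valid[idx] = True
    return out


def correct_displacement(rec: GazeRecording, iv: ArtifactInterval) -> GazeRecording:
    """Reintegrate a spatial displacement from the last trusted position.

    With p0 the last trusted position before onset, the first in-episode
    sample becomes ``p0 + v_pre * dt`` (v_pre = velocity just before the
    onset, 0 if unavailable) and every later in-episode sample adds the
    raw backward difference. A constant-offset episode on a linear trace
    is thereby recovered exactly.

    Raises
    ------
    UncorrectableError
        For unterminated episodes (left raw, reported upstream) or an
        episode with no trusted pre-onset sample.
    """
    if iv.kind != DISPLACEMENT:
        raise UncorrectableError(f"correct_displacement expects a spatial_displacement interval, got {iv.kind}")
    if iv.note == "unterminated":
        raise UncorrectableError("unterminated displacement cannot be reintegrated")
    out = rec.copy()
    idx = _inside(rec, iv)
    if idx.size == 0:
        return out
    i0 = idx[0]
    if i0 == 0 or not rec.valid[i0 - 1]:
        raise UncorrectableError("displacement has no trusted pre-onset anchor")
    p0x, p0y = rec.x[i0 - 1], rec.y[i0 - 1]
    if i0 >= 2 and rec.valid[i0 - 2]:
        dt_pre = rec.t[i0 - 1] - rec.t[i0 - 2]
        vpx = (rec.x[i0 - 1] - rec.x[i0 - 2]) / dt_pre
        vpy = (rec.y[i0 - 1] - rec.y[i0 - 2]) / dt_pre
    else:
        vpx = vpy = 0.0
    dt0 = rec.t[i0] - rec.t[i0 - 1]
    out.x[i0] = p0x + vpx * dt0
    out.y[i0] = p0y + vpy * dt0
    for k in idx[1:]:
        out.x[k] = out.x[k - 1] + (rec.x[k] - rec.x[k - 1])
        out.y[k] = out.y[k - 1] + (rec.y[k] - rec.y[k - 1])
    out.valid[idx] = True
    return out


def correct_blink(rec: GazeRecording, iv: ArtifactInterval, pad_ms: float = 200.0) -> GazeRecording:
    """Discard and linearly refill a blink's padded window.

    The interval extended by ``pad_ms`` on each side (clipped to the
    record) is refilled per axis by the straight line between the last
    trusted sample before the window and the first trusted sample after
    it; at a record boundary the nearest trusted value is held. Refilled
    samples become valid.
    """
    if iv.kind != BLINK:
        raise UncorrectableError(f"correct_blink expects a blink interval, got {iv.kind}")
    if not rec.valid.any():
        raise UncorrectableError("recording has no valid samples to anchor interpolation")
    out = rec.copy()
    lo, hi = iv.start_ms - pad_ms, iv.end_ms + pad_ms
    idx = np.flatnonzero((rec.t >= lo) & (rec.t < hi))
    if idx.size == 0:
        return out
    pre = np.flatnonzero((rec.t < lo) & rec.valid)
    post = np.flatnonzero((rec.t >= hi) & rec.valid)
    if pre.size and post.size:
        i, j = pre[-1], post[0]
        tp = [rec.t[i], rec.t[j]]
        out.x[idx] = np.interp(rec.t[idx], tp, [rec.x[i], rec.x[j]])
        out.y[idx] = np.interp(rec.t[idx], tp, [rec.y[i], rec.y[j]])
    elif post.size:  # gap at record start: hold first trusted value
        out.x[idx] = rec.x[post[0]]
        out.y[idx] = rec.y[post[0]]
    elif pre.size:  # gap at record end: hold last trusted value
        out.x[idx] = rec.x[pre[-1]]
        out.y[idx] = rec.y[pre[-1]]
    else:
        raise UncorrectableError("no trusted sample outside the padded blink window")
    out.valid[idx] = True
    return out


def _merge_windows(windows: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping/touching [lo, hi) windows."""
    merged: list[list[float]] = []
    for lo, hi in sorted(windows):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def detect_artifacts(rec: GazeRecording, cfg: DetectorConfig | None = None) -> list[ArtifactInterval]:
    """All artifact intervals of a recording, sorted by start time.

    Blinks come from the validity mask; sensor episodes are segmented on
    the blink-corrected trace (the flanking excursions of a blink would
    otherwise alias as spikes). The recording itself is not modified.
    """
    cfg = cfg or DetectorConfig()
    blinks = detect_blink_intervals(rec)
    work = rec
    if blinks:
        work = rec.copy()
        for lo, hi in _merge_windows(
            [(iv.start_ms - cfg.blink_pad_ms, iv.end_ms + cfg.blink_pad_ms) for iv in blinks]
        ):
            work = correct_blink(work, ArtifactInterval(kind=BLINK, start_ms=lo, end_ms=hi), pad_ms=0.0)
    episodes = segment_sensor_artifacts(compute_velocity(work), cfg) if len(work) >= 2 else []
    return sorted(blinks + episodes, key=lambda iv: iv.start_ms)


def clean_recording(rec: GazeRecording, cfg: DetectorConfig | None = None) -> tuple[GazeRecording, CleanReport]:
    """Full cleaning pass: blinks, then spikes and displacements.

    Pipeline order: (1) detect blinks from the validity mask, (2) correct
    them with ``cfg.blink_pad_ms`` padding (overlapping padded windows
    merged first), (3) compute velocity on the blink-free trace,
    (4) segment super-threshold episodes, (5) correct spikes (mode=post)
    and terminated displacements in time order; unterminated episodes are
    left raw and counted. Output length and timestamps always equal the
    input's.

    A pass over already-clean data is the identity and reports all-zero
    counts, so the operation is idempotent.
    """
    cfg = cfg or DetectorConfig()
    report = CleanReport(config_used=cfg)
    out = rec.copy()

    blinks = detect_blink_intervals(out)
    report.n_blinks = len(blinks)
    if blinks:
        windows = _merge_windows(
            [(iv.start_ms - cfg.blink_pad_ms, iv.end_ms + cfg.blink_pad_ms) for iv in blinks]
        )
        for lo, hi in windows:
            span = ArtifactInterval(kind=BLINK, start_ms=lo, end_ms=hi)
            n_before = int(out.valid.sum())
            out = correct_blink(out, span, pad_ms=0.0)
            report.samples_interpolated += int(((out.t >= lo) & (out.t < hi)).sum())
            del n_before

    if len(out) >= 2:
        vel = compute_velocity(out)
        episodes = segment_sensor_artifacts(vel, cfg)
    else:
        episodes = []
    for iv in sorted(episodes, key=lambda e: e.start_ms):
        if iv.note == "unterminated":
            report.unterminated += 1
            continue
        n_inside = int(((out.t >= iv.start_ms) & (out.t < iv.end_ms)).sum())
        if iv.kind == SPIKE:
            out = correct_spike(out, iv, mode="post")
            report.n_spikes += 1
        else:
            out = correct_displacement(out, iv)
            report.n_displacements += 1
        report.samples_replaced += n_inside
    return out, report
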