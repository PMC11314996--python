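"""Ground-truthed synthetic gaze generation.

Real participant recordings from the scanner are not redistributable, so
validation rests on synthesis: every generator returns either a clean
trace or an :class:`InjectionTruth` pairing a clean trace, a corrupted
copy and the exact list of injected artifact intervals. The generators
emulate the acquisition world of the target setup -- 1000 Hz monocular
samples on a 1680x1050 px screen viewed at 1 m -- and the two 20 s
bench protocols used to validate cleaning (continuous blinking at the
screen centre; an inside-out spiral scan), plus full 280 s block-design
group sessions with controllable task adherence.

Injected artifacts are detectable by construction: spike and
displacement entry/exit jumps exceed the 40 px/ms threshold in a single
sample period, while genuine synthetic eye movement (fixation jitter,
spiral scanning, inter-target transitions) stays well below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .detection import BLINK, DISPLACEMENT, SPIKE, ArtifactInterval
from .geometry import DEFAULT_GEOMETRY, ScreenGeometry
from .paradigm import AJ, CENTER, NOAJ, BlockSchedule, build_default_schedule
from .quantify import AOI, default_aois
from .recording import GazeRecording

__all__ = [
    "InjectionTruth",
    "ArtifactSpec",
    "MatchScore",
    "generate_fixation_trace",
    "generate_spiral_trace",
    "generate_blink_protocol",
    "inject_artifacts",
    "generate_group_session",
    "score_against_truth",
    "rmse",
]


class SynthError(ValueError):
    """Raised for unsatisfiable generator configurations."""


@dataclass
class InjectionTruth:
    """A clean trace, its corrupted twin, and the ground-truth artifact list."""

    clean: GazeRecording
    dirty: GazeRecording
    artifacts: list[ArtifactInterval]
    seed: int


@dataclass
class ArtifactSpec:
    """How many artifacts of each kind to inject, and their shapes.

    Amplitudes default far above both the detection threshold (one
    sample period at 100 px/ms) and any plausible base-trace noise.
    """

    n_spikes: int = 0
    spike_amp_px: float = 100.0
    spike_len_ms: float = 2.0
    n_displacements: int = 0
    disp_offset_px: float = 100.0
    disp_len_ms: float = 100.0
    n_blinks: int = 0
    blink_len_ms: float = 150.0
    blink_excursion_px: float = 300.0
    blink_excursion_ms: float = 100.0


def _timebase(duration_ms: float, rate_hz: float) -> np.ndarray:
    n = int(round(duration_ms * rate_hz / 1000.0))
    if n < 2:
        raise SynthError("duration too short for the sampling rate")
    return np.arange(n) * (1000.0 / rate_hz)


def generate_fixation_trace(
    duration_ms: float,
    target: tuple[float, float] = (840.0, 525.0),
    noise_sd: float = 1.0,
    rate_hz: float = 1000.0,
    seed: int = 0,
    subject_id: str = "synthetic",
) -> GazeRecording:
    """Steady fixation: Gaussian jitter of ``noise_sd`` px around a target."""
    if noise_sd < 0:
        raise SynthError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = _timebase(duration_ms, rate_hz)
    x = target[0] + rng.normal(0.0, noise_sd, size=t.size)
    y = target[1] + rng.normal(0.0, noise_sd, size=t.size)
    return GazeRecording(t=t, x=x, y=y, subject_id=subject_id, sampling_rate_hz=rate_hz)


def generate_spiral_trace(
    duration_ms: float = 20000.0,
    geom: ScreenGeometry = DEFAULT_GEOMETRY,
    max_speed_px_per_ms: float = 2.0,
    turns: float = 6.0,
    margin_px: float = 50.0,
    rate_hz: float = 1000.0,
    seed: int = 0,
) -> GazeRecording:
    """Inside-out Archimedean spiral scan from the screen centre.

    Constant angular velocity, so the on-screen speed grows with radius;
    the configuration is rejected if the final speed would exceed
    ``max_speed_px_per_ms`` (keep it well under the 40 px/ms detection
    threshold) or the spiral would leave the screen.
    """
    t = _timebase(duration_ms, rate_hz)
    cx, cy = geom.width_px / 2.0, geom.height_px / 2.0
    r_max = min(cx, cy) - margin_px
    if r_max <= 0:
        raise SynthError("margin leaves no room for the spiral")
    theta_f = 2.0 * math.pi * turns
    b = r_max / theta_f
    omega = theta_f / duration_ms  # rad per ms
    v_peak = omega * math.hypot(b, r_max)
    if v_peak > max_speed_px_per_ms:
        raise SynthError(
            f"spiral peak speed {v_peak:.3f} px/ms exceeds max_speed {max_speed_px_per_ms}; "
            "reduce turns or extend the duration"
        )
    theta = omega * t
    r = b * theta
    x = cx + r * np.cos(theta)
    y = cy + r * np.sin(theta)
    return GazeRecording(t=t, x=x, y=y, subject_id="spiral-protocol", sampling_rate_hz=rate_hz)


def _carve_blink(
    rec: GazeRecording,
    i0: int,
    i1: int,
    excursion_px: float,
    excursion_ms: float,
    direction: float,
) -> ArtifactInterval:
    """Null out samples i0..i1 and add the flanking vertical excursions in place."""
    n_exc = max(1, int(round(excursion_ms * rec.sampling_rate_hz / 1000.0)))
    rec.x[i0 : i1 + 1] = np.nan
    rec.y[i0 : i1 + 1] = np.nan
    rec.valid[i0 : i1 + 1] = False
    pre = np.arange(max(0, i0 - n_exc), i0)
    if pre.size:
        ramp = np.linspace(0.0, 1.0, pre.size + 1)[1:]
        rec.y[pre] += direction * excursion_px * ramp
    post = np.arange(i1 + 1, min(len(rec), i1 + 1 + n_exc))
    if post.size:
        ramp = np.linspace(1.0, 0.0, post.size + 1)[:-1]
        rec.y[post] += direction * excursion_px * ramp
    end = rec.t[i1 + 1] if i1 + 1 < len(rec) else rec.t[i1] + rec.dt_ms
    return ArtifactInterval(kind=BLINK, start_ms=float(rec.t[i0]), end_ms=float(end))


def generate_blink_protocol(
    duration_ms: float = 20000.0,
    blink_rate_hz: float = 1.0,
    blink_len_ms: float = 150.0,
    excursion_px: float = 300.0,
    excursion_ms: float = 100.0,
    noise_sd: float = 1.0,
    target: tuple[float, float] = (840.0, 525.0),
    rate_hz: float = 1000.0,
    seed: int = 0,
) -> InjectionTruth:
    """Bench protocol 1: centre fixation with ~1 blink per second.

    Each blink is a null run flanked by sharp vertical excursions of
    ``excursion_ms`` on each side (the gaze appears to shoot up or down
    as the eyelid covers the pupil). Blink onsets are jittered around a
    regular grid, so a 20 s run holds ``duration * rate`` blinks.
    """
    clean = generate_fixation_trace(duration_ms, target, noise_sd, rate_hz, seed=seed)
    rng = np.random.default_rng(seed + 1)
    dirty = clean.copy()
    n_blinks = int(round(duration_ms / 1000.0 * blink_rate_hz))
    period = duration_ms / max(1, n_blinks)
    if blink_len_ms + 2 * excursion_ms > 0.5 * period:
        raise SynthError("blink rate too high: blinks plus excursions would overlap")
    truth: list[ArtifactInterval] = []
    dt = 1000.0 / rate_hz
    n_len = max(1, int(round(blink_len_ms / dt)))
    for k in range(n_blinks):
        centre = (k + 0.5) * period + rng.uniform(-0.1, 0.1) * period
        i0 = int(round((centre - blink_len_ms / 2.0) / dt))
        i0 = max(1, min(i0, len(dirty) - n_len - 1))
        i1 = i0 + n_len - 1
        direction = rng.choice([-1.0, 1.0])
        truth.append(_carve_blink(dirty, i0, i1, excursion_px, excursion_ms, direction))
    truth.sort(key=lambda iv: iv.start_ms)
    return InjectionTruth(clean=clean, dirty=dirty, artifacts=truth, seed=seed)


def inject_artifacts(clean: GazeRecording, spec: ArtifactSpec, seed: int = 0) -> InjectionTruth:
    """Corrupt a clean trace with the requested artifact mix.

    Artifacts are placed uniformly at random without overlap, each with a
    guard margin (wide enough to cover blink padding) and clear of the
    record boundaries so every episode is terminated and anchorable.
    Spikes and displacements add a constant vector offset of random
    direction over their span; blinks null their span and add the
    flanking vertical excursions.

    Raises
    ------
    SynthError
        If the requested artifacts cannot be placed without overlap
        after bounded retries.
    """
    rng = np.random.default_rng(seed)
    dirty = clean.copy()
    dt = dirty.dt_ms
    n = len(dirty)
    truth: list[ArtifactInterval] = []
    reserved: list[tuple[float, float]] = []
    edge_ms = 400.0  # keep clear of boundaries: blink pad + excursions + anchors

    def _place(span_ms: float, guard_ms: float) -> float:
        lo, hi = edge_ms, clean.duration_ms - edge_ms - span_ms
        if hi <= lo:
            raise SynthError("recording too short for the requested artifacts")
        for _ in range(500):
            s = rng.uniform(lo, hi)
            window = (s - guard_ms, s + span_ms + guard_ms)
            if all(window[1] <= a or window[0] >= b for a, b in reserved):
                reserved.append(window)
                return s
        raise SynthError("could not place artifacts without overlap; reduce counts or lengths")

    jobs = (
        [(SPIKE, spec.spike_len_ms, 50.0)] * spec.n_spikes
        + [(DISPLACEMENT, spec.disp_len_ms, 50.0)] * spec.n_displacements
        + [(BLINK, spec.blink_len_ms, 300.0 + spec.blink_excursion_ms)] * spec.n_blinks
    )
    for kind, span_ms, guard_ms in jobs:
        s = _place(span_ms, guard_ms)
        i0 = max(1, int(round(s / dt)))
        n_len = max(1, int(round(span_ms / dt)))
        i1 = min(n - 2, i0 + n_len - 1)
        if kind == BLINK:
            direction = rng.choice([-1.0, 1.0])
            truth.append(_carve_blink(dirty, i0, i1, spec.blink_excursion_px, spec.blink_excursion_ms, direction))
            continue
        phi = rng.uniform(0.0, 2.0 * math.pi)
        amp = spec.spike_amp_px if kind == SPIKE else spec.disp_offset_px
        dx, dy = amp * math.cos(phi), amp * math.sin(phi)
        dirty.x[i0 : i1 + 1] += dx
        dirty.y[i0 : i1 + 1] += dy
        truth.append(
            ArtifactInterval(kind=kind, start_ms=float(dirty.t[i0]), end_ms=float(dirty.t[i1 + 1]))
        )
    truth.sort(key=lambda iv: iv.start_ms)
    return InjectionTruth(clean=clean, dirty=dirty, artifacts=truth, seed=seed)


def _default_adherence() -> dict[str, float]:
    # Stated-world task adherence: fixating the cross is easy (~0.72 of
    # samples in its AOI); AJ/NOAJ target objects hold the mouse for only
    # 3 of each 5 s video, bounding adherence near 0.5.
    return {CENTER: 0.72, AJ: 0.48, NOAJ: 0.50}


def _limit_speed(x: np.ndarray, y: np.ndarray, dt: float, ramp_speed: float) -> None:
    """Replace instantaneous jumps in a piecewise-constant trace by linear
    ramps at ``ramp_speed`` px/ms, in place (saccade-like transitions)."""
    jumps = np.flatnonzero(np.hypot(np.diff(x), np.diff(y)) > ramp_speed * dt) + 1
    for pos, j in enumerate(jumps):
        j_next = jumps[pos + 1] if pos + 1 < len(jumps) else x.size
        px, py = x[j - 1], y[j - 1]
        qx, qy = x[j], y[j]
        dist = math.hypot(qx - px, qy - py)
        n_ramp = max(1, min(int(math.ceil(dist / (ramp_speed * dt))), j_next - j))
        frac = np.linspace(0.0, 1.0, n_ramp + 1)[1:]
        x[j : j + n_ramp] = px + frac * (qx - px)
        y[j : j + n_ramp] = py + frac * (qy - py)


def generate_group_session(
    n_subjects: int = 16,
    sched: BlockSchedule | None = None,
    aois: list[AOI] | None = None,
    geom: ScreenGeometry = DEFAULT_GEOMETRY,
    adherence: dict[str, float] | None = None,
    decay_per_trial: dict[str, float] | None = None,
    trial_sd: float = 0.1,
    subject_sd: float = 0.05,
    noise_sd: float = 1.0,
    artifact_spec: ArtifactSpec | None = None,
    rate_hz: float = 1000.0,
    seed: int = 0,
) -> list[InjectionTruth]:
    """Simulate a cohort of block-design sessions with known adherence.

    Per trial, the subject dwells on the trial's AOI centre (side-matched
    target object, or the cross) for a fraction of the trial and on a
    fixed off-AOI point for the rest. The dwell fraction is
    ``adherence[cond] - decay_per_trial[cond]*(trial_position-1)`` plus a
    subject-level and a trial-level Gaussian perturbation (clipped to
    [0, 1]); transitions between dwell points ramp at ~20 px/ms so no
    genuine movement ever crosses the 40 px/ms artifact threshold. Each
    session is then artifact-injected if ``artifact_spec`` is given.
    """
    sched = sched or build_default_schedule()
    aois = aois if aois is not None else default_aois(geom)
    adherence = adherence or _default_adherence()
    decay_per_trial = decay_per_trial or {}
    centres: dict[tuple[str, str | None], tuple[float, float]] = {}
    for a in aois:
        centres[(a.condition, a.side)] = ((a.x_min + a.x_max) / 2.0, (a.y_min + a.y_max) / 2.0)
    off_point = (geom.width_px / 2.0, geom.height_px * 0.08)  # outside every default AOI

    dt = 1000.0 / rate_hz
    ramp_speed = 20.0  # px/ms, half the detection threshold
    out: list[InjectionTruth] = []
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    for s_idx, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        t = _timebase(sched.session_duration_ms, rate_hz)
        x = np.empty_like(t)
        y = np.empty_like(t)
        subj_shift = rng.normal(0.0, subject_sd)
        for b in sched.blocks:
            for tr in b.trials:
                i0 = int(round(tr.start_ms / dt))
                i1 = int(round(tr.end_ms / dt))
                n_tr = i1 - i0
                key = (b.condition, tr.side)
                target = centres.get(key) or centres.get((b.condition, None)) or off_point
                position = sched.trial_position(b.block_index, tr.trial_index)
                p = adherence.get(b.condition, 0.5)
                p -= decay_per_trial.get(b.condition, 0.0) * (position - 1)
                p = float(np.clip(p + subj_shift + rng.normal(0.0, trial_sd), 0.0, 1.0))
                n_on = int(round(p * n_tr))
                x[i0 : i0 + n_on] = target[0]
                y[i0 : i0 + n_on] = target[1]
                x[i0 + n_on : i1] = off_point[0]
                y[i0 + n_on : i1] = off_point[1]
        _limit_speed(x, y, dt, ramp_speed)
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, size=t.size)
            y = y + rng.normal(0.0, noise_sd, size=t.size)
        clean = GazeRecording(t=t, x=x, y=y, subject_id=f"sim{s_idx + 1:02d}", sampling_rate_hz=rate_hz)
        if artifact_spec is None:
            out.append(InjectionTruth(clean=clean, dirty=clean.copy(), artifacts=[], seed=seed))
        else:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            out.append(inject_artifacts(clean, artifact_spec, seed=sub_seed))
    return out


@dataclass
class MatchScore:
    """Detection quality of a candidate interval list against ground truth."""

    precision: float
    recall: float
    n_matched: int
    n_detected: int
    n_truth: int
    per_kind: dict[str, dict[str, float]] = field(default_factory=dict)
    precision_undefined: bool = False


def score_against_truth(
    detected: list[ArtifactInterval],
    truth: list[ArtifactInterval],
    tol_ms: float = 25.0,
) -> MatchScore:
    """Greedy one-to-one matching of detected vs ground-truth intervals.

    A detected interval matches an unmatched truth interval of the same
    kind whose midpoint lies within ``tol_ms``. Precision with an empty
    detected list is reported as 1 with ``precision_undefined`` set.
    """
    if tol_ms < 0:
        raise SynthError("tol_ms must be non-negative")

    def _match(det: list[ArtifactInterval], tru: list[ArtifactInterval]) -> int:
        used = [False] * len(tru)
        matched = 0
        for d in sorted(det, key=lambda iv: iv.midpoint_ms):
            best, best_gap = None, tol_ms
            for i, g in enumerate(tru):
                if used[i] or g.kind != d.kind:
                    continue
                gap = abs(g.midpoint_ms - d.midpoint_ms)
                if gap <= best_gap:
                    best, best_gap = i, gap
            if best is not None:
                used[best] = True
                matched += 1
        return matched

    per_kind: dict[str, dict[str, float]] = {}
    for kind in (SPIKE, DISPLACEMENT, BLINK):
        det_k = [d for d in detected if d.kind == kind]
        tru_k = [g for g in truth if g.kind == kind]
        if not det_k and not tru_k:
            continue
        m = _match(det_k, tru_k)
        per_kind[kind] = {
            "precision": m / len(det_k) if det_k else 1.0,
            "recall": m / len(tru_k) if tru_k else 1.0,
            "n_detected": len(det_k),
            "n_truth": len(tru_k),
            "n_matched": m,
        }
    n_matched = int(sum(v["n_matched"] for v in per_kind.values()))
    return MatchScore(
        precision=n_matched / len(detected) if detected else 1.0,
        recall=n_matched / len(truth) if truth else 1.0,
        n_matched=n_matched,
        n_detected=len(detected),
        n_truth=len(truth),
        per_kind=per_kind,
        precision_undefined=not detected,
    )


def rmse(a: GazeRecording, b: GazeRecording) -> float:
    """Root-mean-square 2-D position error over samples valid in both."""
    if len(a) != len(b):
        raise SynthError("recordings must have equal length")
    m = a.valid & b.valid
    if not m.any():
        return float("nan")
    return float(np.sqrt(np.mean((a.x[m] - b.x[m]) ** 2 + (a.y[m] - b.y[m]) ** 2)))
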