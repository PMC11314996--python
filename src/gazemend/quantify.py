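"""On-screen and task-specific (AOI) gaze-position rates.

At a uniform sampling rate, the number of gaze samples in a region is
proportional to dwell time, so all rates are sample-count fractions:

* the **on-screen rate** of a condition is the fraction of its samples
  that are valid and inside the screen bounds (half-open
  ``0 <= x < width_px``, ``0 <= y < height_px``);
* the **task rate** is the fraction inside any applicable area of
  interest (AOI) -- the cross box during Center, the side-matched target
  object box during AJ/NOAJ.

Null (lost) samples count against both rates, in the raw as in the
filtered variant; cleaning interpolates them back, which is exactly how
filtering can legitimately raise a rate.

The default AOI geometry is a documented placeholder (the stimulus
layout is not part of any data file): a 200x200 px box on the screen
centre for the cross, 400x400 px object boxes centred at 1/4 and 3/4 of
the screen width. Override from config for a real stimulus set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry
from .paradigm import AJ, CENTER, NOAJ, BlockSchedule, assign_condition
from .recording import GazeRecording

__all__ = [
    "AOI",
    "AdherenceResult",
    "default_aois",
    "onscreen_rate",
    "aoi_rate",
    "trial_rates",
    "adherence_table",
]


class QuantifyError(ValueError):
    """Raised for undefined rates or missing AOI configuration."""


@dataclass(frozen=True)
class AOI:
    """Half-open axis-aligned box ``[x_min,x_max) x [y_min,y_max)`` in px."""

    label: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    condition: str
    side: str | None = None  # restrict to trials with this target side

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise QuantifyError(f"AOI {self.label!r} has an empty box")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.x_min) & (x < self.x_max) & (y >= self.y_min) & (y < self.y_max)


def default_aois(geom: ScreenGeometry = DEFAULT_GEOMETRY) -> list[AOI]:
    """Placeholder AOI set: centred cross box + left/right object boxes."""
    cx, cy = geom.width_px / 2.0, geom.height_px / 2.0
    aois = [AOI("cross", cx - 100, cx + 100, cy - 100, cy + 100, condition=CENTER)]
    for cond in (AJ, NOAJ):
        for side, ox in (("left", geom.width_px * 0.25), ("right", geom.width_px * 0.75)):
            aois.append(
                AOI(f"object_{side}", ox - 200, ox + 200, cy - 200, cy + 200, condition=cond, side=side)
            )
    return aois


def onscreen_rate(
    rec: GazeRecording,
    geom: ScreenGeometry,
    labels: pd.DataFrame,
    condition: str,
) -> float:
    """Fraction of a condition's samples that are valid and on-screen."""
    sel = (labels["condition"] == condition).to_numpy()
    if not sel.any():
        raise QuantifyError(f"no samples labelled {condition!r}")
    ok = (
        rec.valid[sel]
        & (rec.x[sel] >= 0)
        & (rec.x[sel] < geom.width_px)
        & (rec.y[sel] >= 0)
        & (rec.y[sel] < geom.height_px)
    )
    return float(ok.mean())


def _aoi_hit_mask(rec: GazeRecording, aois: list[AOI], labels: pd.DataFrame, condition: str) -> tuple[np.ndarray, np.ndarray]:
    """(selection mask for the condition, in-AOI mask over the whole record)."""
    applicable = [a for a in aois if a.condition == condition]
    if not applicable:
        raise QuantifyError(f"no AOI applies to condition {condition!r}")
    sel = (labels["condition"] == condition).to_numpy()
    if not sel.any():
        raise QuantifyError(f"no samples labelled {condition!r}")
    side = labels["side"].to_numpy()
    hit = np.zeros(len(rec), dtype=bool)
    for a in applicable:
        m = a.contains(rec.x, rec.y) & rec.valid & sel
        if a.side is not None:
            m &= side == a.side
        hit |= m
    return sel, hit


def aoi_rate(rec: GazeRecording, aois: list[AOI], labels: pd.DataFrame, condition: str) -> float:
    """Fraction of a condition's samples inside any applicable AOI.

    AOIs carrying a side only count on trials with that target side. The
    denominator is every sample of the condition (valid or not).
    """
    sel, hit = _aoi_hit_mask(rec, aois, labels, condition)
    return float(hit[sel].mean())


def trial_rates(
    rec: GazeRecording,
    sched: BlockSchedule,
    aois: list[AOI],
    t0_ms: float | None = None,
    average: bool = True,
) -> pd.DataFrame:
    """Task rate per (condition, temporal trial position).

    The temporal position is the within-block trial index for AJ/NOAJ
    (positions 1..5, averaged over the four block repeats) and the block
    occurrence number for the single-trial Center blocks (positions
    1..4). With ``average=False`` one row per (condition, block, trial)
    occurrence is returned, with its position alongside.
    """
    labels = assign_condition(rec, sched, t0_ms=t0_ms)
    rows = []
    for cond in (AJ, NOAJ, CENTER):
        if not any(b.condition == cond for b in sched.blocks):
            continue
        sel, hit = _aoi_hit_mask(rec, aois, labels, cond)
        blk = labels["block"].to_numpy()
        tri = labels["trial"].to_numpy()
        for b in sched.condition_blocks(cond):
            for tr in b.trials:
                m = sel & (blk == b.block_index) & (tri == tr.trial_index)
                if not m.any():
                    continue
                rows.append(
                    {
                        "condition": cond,
                        "block": b.block_index,
                        "trial": tr.trial_index,
                        "position": sched.trial_position(b.block_index, tr.trial_index),
                        "rate": float(hit[m].mean()),
                    }
                )
    df = pd.DataFrame(rows)
    if average and not df.empty:
        df = (
            df.groupby(["condition", "position"], as_index=False)["rate"]
            .mean()
            .sort_values(["condition", "position"], ignore_index=True)
        )
    return df


@dataclass
class AdherenceResult:
    """Screen and task adherence of one subject under one condition/variant."""

    subject_id: str
    condition: str
    variant: str  # "original" | "filtered"
    onscreen_rate: float
    task_rate: float
    per_trial_rates: list[float] = field(default_factory=list)


def adherence_table(
    original: GazeRecording,
    filtered: GazeRecording,
    sched: BlockSchedule,
    aois: list[AOI],
    geom: ScreenGeometry = DEFAULT_GEOMETRY,
    t0_ms: float | None = None,
) -> pd.DataFrame:
    """Original-vs-filtered adherence summary, one row per (condition, variant)."""
    rows = []
    for variant, rec in (("original", original), ("filtered", filtered)):
        labels = assign_condition(rec, sched, t0_ms=t0_ms)
        tr = trial_rates(rec, sched, aois, t0_ms=t0_ms)
        for cond in (AJ, NOAJ, CENTER):
            per_trial = tr.loc[tr["condition"] == cond, "rate"].tolist()
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "condition": cond,
                    "variant": variant,
                    "onscreen_rate": onscreen_rate(rec, geom, labels, cond),
                    "task_rate": aoi_rate(rec, aois, labels, cond),
                    "per_trial_rates": per_trial,
                }
            )
    return pd.DataFrame(rows)
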