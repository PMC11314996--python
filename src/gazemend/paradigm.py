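"""Block/trial structure of the joint-attention task, and time-to-condition mapping.

The default session is the 280 s block design: four repeats of
[25 s AJ (5 videos), 25 s NOAJ (5 videos), 20 s central cross], i.e.
12 blocks and 44 trials. "AJ" blocks show an interlocutor shifting gaze
to a left or right target object (joint attention), "NOAJ" the matched
no-shift control, "Center" a fixation cross. AJ/NOAJ trials carry a
left/right side attribute, balanced across the session, which AOI
scoring consumes.

All spans are half-open ``[start, end)`` in milliseconds from session
onset; a sample exactly on a boundary belongs to the later block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import GazeRecording

__all__ = [
    "AJ",
    "NOAJ",
    "CENTER",
    "Trial",
    "Block",
    "BlockSchedule",
    "build_default_schedule",
    "assign_condition",
]

AJ = "AJ"
NOAJ = "NOAJ"
CENTER = "Center"
CONDITIONS = (AJ, NOAJ, CENTER)

#: MRI-ET synchronisation period (one fMRI volume), kept for bookkeeping.
TR_MS = 2500.0


class ScheduleError(ValueError):
    """Raised for malformed block schedules."""


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation inside a block; times relative to session onset."""

    trial_index: int  # 1-based position within its block
    start_ms: float
    duration_ms: float
    side: str | None = None  # "left" | "right" for AJ/NOAJ, None for Center

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.duration_ms


@dataclass(frozen=True)
class Block:
    block_index: int  # 1-based position within the session
    condition: str
    start_ms: float
    duration_ms: float
    trials: tuple[Trial, ...]

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.duration_ms


@dataclass
class BlockSchedule:
    """Ordered, contiguous blocks tiling a session."""

    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        self.blocks = tuple(self.blocks)
        t = 0.0
        for b in self.blocks:
            if b.condition not in CONDITIONS:
                raise ScheduleError(f"unknown condition {b.condition!r}")
            if abs(b.start_ms - t) > 1e-9:
                raise ScheduleError(f"block {b.block_index} starts at {b.start_ms}, expected {t} (blocks must tile)")
            tt = b.start_ms
            for tr in b.trials:
                if abs(tr.start_ms - tt) > 1e-9:
                    raise ScheduleError(f"trial {tr.trial_index} of block {b.block_index} does not tile its block")
                tt = tr.end_ms
            if abs(tt - b.end_ms) > 1e-9:
                raise ScheduleError(f"trials of block {b.block_index} do not cover the block")
            t = b.end_ms

    @property
    def session_duration_ms(self) -> float:
        return sum(b.duration_ms for b in self.blocks)

    @property
    def n_trials(self) -> int:
        return sum(len(b.trials) for b in self.blocks)

    def condition_blocks(self, condition: str) -> list[Block]:
        return [b for b in self.blocks if b.condition == condition]

    def trial_position(self, block_index: int, trial_index: int) -> int:
        """Temporal trial position used for across-trial (fatigue) analyses.

        For multi-trial blocks this is the within-block trial index
        (position 1..5 for AJ/NOAJ, averaged over block repeats). A
        single-trial block contributes its occurrence number among its
        condition's blocks instead, so the four Center presentations are
        temporal positions 1..4.
        """
        block = next(b for b in self.blocks if b.block_index == block_index)
        if len(block.trials) > 1:
            return trial_index
        siblings = self.condition_blocks(block.condition)
        return siblings.index(block) + 1

    def n_trial_positions(self, condition: str) -> int:
        """Number of distinct temporal trial positions for a condition."""
        blocks = self.condition_blocks(condition)
        if not blocks:
            return 0
        return max(self.trial_position(b.block_index, tr.trial_index) for b in blocks for tr in b.trials)


def build_default_schedule(side_seed: int | None = None) -> BlockSchedule:
    """The 280 s default session: 4 x [25 s AJ, 25 s NOAJ, 20 s Center].

    12 blocks, 44 trials (20 AJ, 20 NOAJ, 4 Center). AJ and NOAJ trials
    alternate left/right target sides (10/10 per condition); pass
    ``side_seed`` to shuffle the balanced side assignment instead.
    """
    sides = {}
    for cond in (AJ, NOAJ):
        s = ["left", "right"] * 10
        if side_seed is not None:
            rng = np.random.default_rng(side_seed)
            rng.shuffle(s)
        sides[cond] = s

    blocks: list[Block] = []
    t = 0.0
    bi = 0
    counters = {AJ: 0, NOAJ: 0}
    for _ in range(4):
        for cond, dur_s, n_trials in ((AJ, 25.0, 5), (NOAJ, 25.0, 5), (CENTER, 20.0, 1)):
            bi += 1
            dur = dur_s * 1000.0
            trial_dur = dur / n_trials
            trials = []
            for k in range(n_trials):
                side = None
                if cond in sides:
                    side = sides[cond][counters[cond]]
                    counters[cond] += 1
                trials.append(Trial(trial_index=k + 1, start_ms=t + k * trial_dur, duration_ms=trial_dur, side=side))
            blocks.append(Block(block_index=bi, condition=cond, start_ms=t, duration_ms=dur, trials=tuple(trials)))
            t += dur
    return BlockSchedule(blocks=tuple(blocks))


def assign_condition(rec: GazeRecording, sched: BlockSchedule, t0_ms: float | None = None) -> pd.DataFrame:
    """Label every sample with its (condition, block, trial, side).

    ``t0_ms`` is the session onset on the recording's clock and defaults
    to the first timestamp (override it for MRI-trigger alignment).
    Samples outside ``[t0, t0 + session_duration)`` get condition "none"
    and block/trial 0. Spans are half-open, so a sample exactly on a
    boundary belongs to the later block/trial.
    """
    if t0_ms is None:
        t0_ms = float(rec.t[0]) if len(rec) else 0.0
    tau = rec.t - t0_ms
    n = len(rec)
    cond = np.full(n, "none", dtype=object)
    block = np.zeros(n, dtype=np.int64)
    trial = np.zeros(n, dtype=np.int64)
    side = np.full(n, "", dtype=object)

    starts = np.array([b.start_ms for b in sched.blocks])
    in_session = (tau >= 0) & (tau < sched.session_duration_ms)
    if not in_session.any():
        warnings.warn("recording lies entirely outside the session; all labels are 'none'", stacklevel=2)
    bidx = np.searchsorted(starts, tau[in_session], side="right") - 1
    sel = np.flatnonzero(in_session)
    for bi in np.unique(bidx):
        b = sched.blocks[bi]
        here = sel[bidx == bi]
        cond[here] = b.condition
        block[here] = b.block_index
        tstarts = np.array([tr.start_ms for tr in b.trials])
        tidx = np.searchsorted(tstarts, tau[here], side="right") - 1
        trial[here] = [b.trials[k].trial_index for k in tidx]
        side[here] = [b.trials[k].side or "" for k in tidx]
    return pd.DataFrame(
        {"time_ms": rec.t, "condition": cond, "block": block, "trial": trial, "side": side}
    )
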