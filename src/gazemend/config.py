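"""YAML/JSON configuration plumbing.

A single config file can hold any of the blocks ``geometry``,
``detector``, ``aois`` and ``schedule``; each loader pulls its block and
falls back to the package defaults for anything absent.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .detection import DetectorConfig
from .geometry import DEFAULT_GEOMETRY, ScreenGeometry
from .paradigm import Block, BlockSchedule, Trial, build_default_schedule
from .quantify import AOI, default_aois

__all__ = [
    "load_config",
    "geometry_from_config",
    "detector_from_config",
    "aois_from_config",
    "schedule_from_config",
]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def geometry_from_config(cfg: dict) -> ScreenGeometry:
    block = cfg.get("geometry")
    if not block:
        return DEFAULT_GEOMETRY
    return ScreenGeometry(
        width_px=int(block["width_px"]),
        height_px=int(block["height_px"]),
        width_m=float(block["width_m"]),
        height_m=float(block["height_m"]),
        viewing_distance_m=float(block["viewing_distance_m"]),
    )


def detector_from_config(cfg: dict) -> DetectorConfig:
    block = cfg.get("detector", {})
    return DetectorConfig(**{k: float(v) for k, v in block.items()})


def aois_from_config(cfg: dict) -> list[AOI]:
    block = cfg.get("aois")
    if not block:
        return default_aois(geometry_from_config(cfg))
    return [
        AOI(
            label=a["label"],
            x_min=float(a["x_min"]),
            x_max=float(a["x_max"]),
            y_min=float(a["y_min"]),
            y_max=float(a["y_max"]),
            condition=a["condition"],
            side=a.get("side"),
        )
        for a in block
    ]


def schedule_from_config(cfg: dict) -> BlockSchedule:
    block = cfg.get("schedule")
    if not block:
        return build_default_schedule()
    blocks = []
    t = 0.0
    for bi, b in enumerate(block, start=1):
        dur = float(b["duration_ms"])
        n_trials = int(b.get("n_trials", 1))
        sides = b.get("sides") or [None] * n_trials
        trial_dur = dur / n_trials
        trials = tuple(
            Trial(trial_index=k + 1, start_ms=t + k * trial_dur, duration_ms=trial_dur, side=sides[k])
            for k in range(n_trials)
        )
        blocks.append(Block(block_index=bi, condition=b["condition"], start_ms=t, duration_ms=dur, trials=trials))
        t += dur
    return BlockSchedule(blocks=tuple(blocks))
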