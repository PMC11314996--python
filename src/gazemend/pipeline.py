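"""End-to-end orchestration: simulate -> clean -> quantify -> stats.

These functions are the scripting surface of the package (there is no
command-line entry point; the `examples/` scripts show typical runs).
Every step writes its outputs plus a provenance JSON (seed, config,
package version) into a run directory and never mutates its inputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correction import clean_recording
from .detection import DetectorConfig, intervals_to_tsv
from .geometry import DEFAULT_GEOMETRY, ScreenGeometry
from .io import read_samples_csv, write_samples_csv
from .paradigm import AJ, CENTER, NOAJ, BlockSchedule, build_default_schedule
from .quantify import AOI, adherence_table, default_aois
from .stats import friedman, posthoc_pairs, wilcoxon_signed_rank
from .synth import ArtifactSpec, generate_group_session

__all__ = ["simulate_session_files", "clean_file", "quantify_files", "stats_from_adherence", "run_pipeline"]


def _provenance(outdir: Path, name: str, seed: int | None, config: dict) -> None:
    payload = {"tool": "gazemend", "version": __version__, "step": name, "seed": seed, "config": config}
    (outdir / f"{name}.provenance.json").write_text(json.dumps(payload, indent=2, default=str))


def simulate_session_files(
    outdir: str | Path,
    n_subjects: int = 16,
    artifact_spec: ArtifactSpec | None = None,
    seed: int = 0,
    **session_kwargs,
) -> list[Path]:
    """Write a simulated cohort as per-subject raw/truth CSV pairs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = artifact_spec if artifact_spec is not None else ArtifactSpec(n_spikes=6, n_displacements=4, n_blinks=10)
    sessions = generate_group_session(n_subjects=n_subjects, artifact_spec=spec, seed=seed, **session_kwargs)
    paths = []
    for s in sessions:
        raw = outdir / f"{s.dirty.subject_id}_raw.csv"
        write_samples_csv(s.dirty, raw)
        write_samples_csv(s.clean, outdir / f"{s.clean.subject_id}_truth.csv")
        intervals_to_tsv(s.artifacts, outdir / f"{s.dirty.subject_id}_truth_artifacts.tsv")
        paths.append(raw)
    _provenance(outdir, "simulate", seed, {"n_subjects": n_subjects, "artifact_spec": dataclasses.asdict(spec)})
    return paths


def clean_file(
    in_path: str | Path,
    out_path: str | Path,
    cfg: DetectorConfig | None = None,
    report_path: str | Path | None = None,
    artifacts_path: str | Path | None = None,
):
    """Clean one recording file; optionally write the audit report."""
    rec = read_samples_csv(in_path, subject_id=Path(in_path).stem.replace("_raw", ""))
    cleaned, report = clean_recording(rec, cfg)
    write_samples_csv(cleaned, out_path)
    if report_path:
        report.to_json(report_path)
    return cleaned, report


def quantify_files(
    raw_paths: list[Path],
    clean_paths: list[Path],
    out_csv: str | Path,
    sched: BlockSchedule | None = None,
    aois: list[AOI] | None = None,
    geom: ScreenGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Adherence table over a cohort of (raw, cleaned) recording pairs."""
    sched = sched or build_default_schedule()
    aois = aois if aois is not None else default_aois(geom)
    frames = []
    for raw_p, clean_p in zip(raw_paths, clean_paths):
        raw = read_samples_csv(raw_p, subject_id=Path(raw_p).stem.replace("_raw", ""))
        cleaned = read_samples_csv(clean_p, subject_id=raw.subject_id)
        frames.append(adherence_table(raw, cleaned, sched, aois, geom))
    df = pd.concat(frames, ignore_index=True)
    df.drop(columns=["per_trial_rates"]).to_csv(out_csv, index=False)
    return df


def stats_from_adherence(df: pd.DataFrame, out_json: str | Path | None = None) -> dict:
    """The group statistical battery on an adherence table.

    Per condition: paired Wilcoxon of filtered vs original on-screen
    rates across subjects; plus, per condition, a Friedman test over the
    per-trial task rates with Bonferroni post hoc pairs.
    """
    results: dict = {"wilcoxon_screen": {}, "friedman_trials": {}}
    for cond in (CENTER, AJ, NOAJ):
        sub = df[df["condition"] == cond]
        ori = sub[sub["variant"] == "original"].sort_values("subject_id")
        fil = sub[sub["variant"] == "filtered"].sort_values("subject_id")
        if len(ori) and len(ori) == len(fil):
            res = wilcoxon_signed_rank(fil["onscreen_rate"].to_numpy(), ori["onscreen_rate"].to_numpy())
            results["wilcoxon_screen"][cond] = dataclasses.asdict(res)
            mat = np.vstack(fil["per_trial_rates"].to_list())
            if mat.shape[1] >= 2:
                fr = friedman(mat)
                results["friedman_trials"][cond] = {
                    "friedman": dataclasses.asdict(fr),
                    "posthoc": [dataclasses.asdict(r) for r in posthoc_pairs(mat)],
                }
    if out_json:
        Path(out_json).write_text(json.dumps(results, indent=2, default=str))
    return results


def run_pipeline(
    outdir: str | Path,
    n_subjects: int = 16,
    seed: int = 0,
    cfg: DetectorConfig | None = None,
    **session_kwargs,
) -> dict:
    """Full synthetic workflow into one run directory; returns the stats dict."""
    outdir = Path(outdir)
    raw_paths = simulate_session_files(outdir / "simulate", n_subjects=n_subjects, seed=seed, **session_kwargs)
    clean_dir = outdir / "clean"
    clean_dir.mkdir(parents=True, exist_ok=True)
    clean_paths = []
    for p in raw_paths:
        out_p = clean_dir / p.name.replace("_raw", "_clean")
        clean_file(p, out_p, cfg=cfg, report_path=clean_dir / (p.stem + "_report.json"))
        clean_paths.append(out_p)
    _provenance(clean_dir, "clean", seed, dataclasses.asdict(cfg or DetectorConfig()))
    qdir = outdir / "quantify"
    qdir.mkdir(parents=True, exist_ok=True)
    df = quantify_files(raw_paths, clean_paths, qdir / "adherence.csv")
    _provenance(qdir, "quantify", seed, {})
    sdir = outdir / "stats"
    sdir.mkdir(parents=True, exist_ok=True)
    results = stats_from_adherence(df, sdir / "stats.json")
    _provenance(sdir, "stats", seed, {})
    return results
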