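"""Reading and writing sample-level gaze recordings.

Two dialects are supported:

* a plain CSV with header ``time_ms,x_px,y_px,valid`` (``valid`` optional);
  empty cells, ``NaN`` tokens, ``.`` tokens or ``valid=0`` all normalise to
  a null sample;
* the sample-line subset of an EyeLink ASC export (monocular), i.e. lines
  of the form ``<time> <x> <y> <pupil> ...``. Event lines (SFIX, ESACC,
  EBLINK, MSG, ...) are ignored on purpose: this package re-derives all
  classification from the raw samples instead of trusting the tracker's
  online parser.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import GazeRecording, RecordingError

__all__ = [
    "read_samples_csv",
    "write_samples_csv",
    "read_eyelink_asc_samples",
    "AscParseReport",
]

_MISSING_TOKENS = {"", ".", "nan", "NaN", "NAN", "na", "NA"}


class FormatError(ValueError):
    """Raised for malformed input files."""


def read_samples_csv(path: str | Path, subject_id: str = "", sampling_rate_hz: float = 1000.0) -> GazeRecording:
    """Read a gaze recording from the package CSV dialect.

    Mandatory columns: ``time_ms``, ``x_px``, ``y_px``. An optional
    ``valid`` column (0/1) forces samples invalid; missing/NaN/'.'
    position cells are invalid regardless.

    Raises
    ------
    FormatError
        If a mandatory column is absent or timestamps are not strictly
        increasing.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("time_ms", "x_px", "y_px"):
        if col not in df.columns:
            raise FormatError(f"mandatory column {col!r} missing from {path}")

    def _num(series: pd.Series) -> np.ndarray:
        s = series.str.strip()
        s = s.where(~s.isin(_MISSING_TOKENS), other="nan")
        return pd.to_numeric(s, errors="coerce").to_numpy(dtype=np.float64)

    t = _num(df["time_ms"])
    if np.any(~np.isfinite(t)):
        raise FormatError(f"non-numeric timestamps in {path}")
    x = _num(df["x_px"])
    y = _num(df["y_px"])
    valid = np.isfinite(x) & np.isfinite(y)
    if "valid" in df.columns:
        flag = _num(df["valid"])
        valid &= np.nan_to_num(flag, nan=0.0) != 0.0
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    try:
        return GazeRecording(t=t, x=x, y=y, valid=valid, subject_id=subject_id, sampling_rate_hz=sampling_rate_hz)
    except RecordingError as e:
        raise FormatError(f"{path}: {e}") from e


def write_samples_csv(rec: GazeRecording, path: str | Path) -> Path:
    """Write a recording in the package CSV dialect.

    Null samples are serialised with empty position cells and ``valid=0``,
    so the round trip through :func:`read_samples_csv` is lossless (and
    byte-stable on a second pass: floats are formatted with Python's
    shortest exact repr).
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ms", "x_px", "y_px", "valid"])
        for t, x, y, v in zip(rec.t, rec.x, rec.y, rec.valid):
            if v:
                w.writerow([repr(float(t)), repr(float(x)), repr(float(y)), 1])
            else:
                w.writerow([repr(float(t)), "", "", 0])
    return path


@dataclass
class AscParseReport:
    """Per-file parse accounting for ASC input."""

    n_samples: int = 0
    n_event_lines: int = 0
    n_skipped: int = 0
    skipped_lines: list[int] = field(default_factory=list)


def read_eyelink_asc_samples(
    path: str | Path,
    subject_id: str = "",
    sampling_rate_hz: float = 1000.0,
    return_report: bool = False,
) -> GazeRecording | tuple[GazeRecording, AscParseReport]:
    """Read the monocular sample lines of an EyeLink ASC export.

    A sample line starts with a numeric timestamp followed by x, y and
    pupil fields; position fields holding the missing-data token ``.``
    yield ``valid=False``. Anything whose first token is not numeric is an
    event line and is skipped silently; a numeric-first line that cannot
    be parsed is skipped with a warning and counted in the report.

    Raises
    ------
    FormatError
        If the file contains no sample lines at all.
    """
    report = AscParseReport()
    ts: list[float] = []
    xs: list[float] = []
    ys: list[float] = []
    ok: list[bool] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                t = float(parts[0])
            except ValueError:
                report.n_event_lines += 1
                continue
            try:
                if len(parts) < 3:
                    raise ValueError("too few fields")
                xtok, ytok = parts[1], parts[2]
                if xtok in _MISSING_TOKENS or ytok in _MISSING_TOKENS:
                    ts.append(t)
                    xs.append(np.nan)
                    ys.append(np.nan)
                    ok.append(False)
                else:
                    ts.append(t)
                    xs.append(float(xtok))
                    ys.append(float(ytok))
                    ok.append(True)
                report.n_samples += 1
            except ValueError:
                report.n_skipped += 1
                report.skipped_lines.append(lineno)
                warnings.warn(f"{path}:{lineno}: unparseable sample line skipped", stacklevel=2)
    if not ts:
        raise FormatError(f"{path}: no sample lines found")
    rec = GazeRecording(
        t=np.asarray(ts),
        x=np.asarray(xs),
        y=np.asarray(ys),
        valid=np.asarray(ok),
        subject_id=subject_id,
        sampling_rate_hz=sampling_rate_hz,
    )
    if return_report:
        return rec, report
    return rec
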