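"""Quick-look QC figure: raw vs cleaned trace, path and time-position views."""

from __future__ import annotations

import numpy as np

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry
from .recording import GazeRecording

__all__ = ["qc_figure"]


def qc_figure(raw: GazeRecording, cleaned: GazeRecording, geom: ScreenGeometry = DEFAULT_GEOMETRY):
    """2x2 panel figure: screen-path and time-position plots, raw vs cleaned.

    Returns the matplotlib Figure; the caller saves or shows it.
    """
    import matplotlib.pyplot as plt  # deferred: headless pipelines skip the import

    fig, axes = plt.subplots(2, 2, figsize=(11, 7), constrained_layout=True)
    for col, (rec, title) in enumerate(((raw, "raw"), (cleaned, "cleaned"))):
        ax = axes[0][col]
        ax.plot(rec.x[rec.valid], rec.y[rec.valid], lw=0.4, color="tab:blue")
        ax.set(title=f"{title} path", xlim=(0, geom.width_px), ylim=(geom.height_px, 0),
               xlabel="x (px)", ylabel="y (px)")
        ax = axes[1][col]
        t_s = rec.t / 1000.0
        ax.plot(t_s, np.where(rec.valid, rec.x, np.nan), lw=0.5, color="tab:red", label="x")
        ax.plot(t_s, np.where(rec.valid, rec.y, np.nan), lw=0.5, color="tab:green", label="y")
        n_null = int((~rec.valid).sum())
        ax.set(title=f"{title} time-position ({n_null} null samples)",
               xlabel="time (s)", ylabel="position (px)")
        ax.legend(loc="upper right", fontsize=8)
    return fig
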