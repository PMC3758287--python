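"""3D track visualisation: x/y in-plane, time on the vertical axis.

The slope of a line encodes speed — near-vertical lines are slow or
stationary cells, shallow lines are fast movers — and the overall drift of
the bundle shows the population's direction of migration.  An optional DIC
reference plane can be drawn at t=0 and the wound rectangle overlaid.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .tracking import TrackSet


def plot_tracks_3d(
    trackset: TrackSet,
    out_path: str | Path,
    dic_image: np.ndarray | None = None,
    wound_rectangle=None,
    min_length: int = 1,
) -> Path:
    """Render every track as a coloured polyline rising in time.

    ``dic_image`` (2D) is drawn as a greyscale plane at t=0;
    ``wound_rectangle`` is ``(x_min, x_max, y_min, y_max)``.
    """
    if trackset.n_tracks == 0:
        raise ValueError("no tracks to plot")
    fig = plt.figure(figsize=(8, 7))
    ax = fig.add_subplot(projection="3d")
    cmap = plt.get_cmap("tab20")
    for i, tid in enumerate(sorted(trackset.tracks)):
        df = trackset.track_dataframe(tid)
        if len(df) < min_length:
            continue
        ax.plot(df["x"], df["y"], df["t"], color=cmap(i % 20), lw=1.5, label=f"track {tid}")
    if dic_image is not None:
        img = np.asarray(dic_image, dtype=float)
        img = (img - img.min()) / max(float(np.ptp(img)), 1e-12)
        ys = np.arange(img.shape[0])
        xs = np.arange(img.shape[1])
        xx, yy = np.meshgrid(xs, ys)
        ax.plot_surface(xx, yy, np.zeros_like(xx), rstride=8, cstride=8,
                        facecolors=plt.cm.gray(img), shade=False, alpha=0.5)
    if wound_rectangle is not None:
        x0, x1, y0, y1 = wound_rectangle
        ax.plot([x0, x1, x1, x0, x0], [y0, y0, y1, y1, y0], [0] * 5, "k-", lw=2)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_zlabel("t (frames)")
    ax.invert_yaxis()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path


def plot_sweep(sweep, out_path: str | Path, label: str = "") -> Path:
    """D_AG / D_GA versus threshold fraction."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sweep.fractions, sweep.d_ag, "o-", label="D_AG")
    ax.plot(sweep.fractions, sweep.d_ga, "s--", label="D_GA")
    ax.set_xlabel("threshold fraction")
    ax.set_ylabel("mean centroid distance (px)")
    if label:
        ax.set_title(label)
    ax.legend()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
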