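"""Scoring automatic tracks against a gold standard.

Two complementary centroid-distance measures expose the two failure modes of
a tracker: D_AG, the mean distance from automatically tracked positions to
the time-matched nearest gold-standard positions, grows when spurious tracks
are produced (e.g. noise segmented as cells at low thresholds); D_GA, the
reverse, grows when true cells are missed (e.g. faint cells lost at high
thresholds).  The threshold-robustness sweep reruns the whole
segment-and-track pipeline while rescaling the automatic thresholds and
reports both measures per threshold fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthesis import GoldStandard
from .tracking import TrackSet


@dataclass
class TrackDistanceReport:
    """Node-wise centroid distances between automatic and gold tracks.

    ``d_ag``/``d_ga`` are means over matched nodes (medians also reported);
    nodes at time points absent from the other set are excluded from the
    mean and counted in ``unmatched_auto``/``unmatched_gold``.
    """

    d_ag: float
    d_ga: float
    d_ag_median: float
    d_ga_median: float
    unmatched_auto: int
    unmatched_gold: int
    per_track_auto: dict = field(default_factory=dict)
    per_track_gold: dict = field(default_factory=dict)


def _as_table(obj) -> pd.DataFrame:
    if isinstance(obj, TrackSet):
        df = obj.nodes[obj.nodes["track_id"].notna()]
        return df.rename(columns={"track_id": "group"})[["group", "t", "x", "y", "z"]]
    if isinstance(obj, GoldStandard):
        if len(obj.table) == 0:
            return pd.DataFrame(columns=["group", "t", "x", "y", "z"])
        return obj.table.rename(columns={"cell_id": "group"})[["group", "t", "x", "y", "z"]]
    df = pd.DataFrame(obj)
    if len(df) == 0:
        return pd.DataFrame(columns=["group", "t", "x", "y", "z"])
    group_col = "track_id" if "track_id" in df.columns else "cell_id"
    return df.rename(columns={group_col: "group"})[["group", "t", "x", "y", "z"]]


def _directed(a: pd.DataFrame, b: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    """Distance from every node of ``a`` to the nearest node of ``b`` at the same t."""
    b_by_t = {t: g[["x", "y", "z"]].to_numpy(dtype=float) for t, g in b.groupby("t")}
    dists, groups, unmatched = [], [], 0
    for row in a.itertuples():
        pts = b_by_t.get(int(row.t))
        if pts is None or len(pts) == 0:
            unmatched += 1
            continue
        d = np.linalg.norm(pts - np.array([row.x, row.y, row.z]), axis=1).min()
        dists.append(float(d))
        groups.append(row.group)
    return np.asarray(dists), np.asarray(groups), unmatched


def track_set_distance(auto, gold, scale: tuple[float, float, float] = (1, 1, 1)) -> TrackDistanceReport:
    """Compute D_AG and D_GA between an automatic track set and a gold standard.

    ``auto`` and ``gold`` may be :class:`~phagotrack.tracking.TrackSet`,
    :class:`~phagotrack.synthesis.GoldStandard` or any node table with
    ``t/x/y/z`` and a track/cell id column.  ``scale`` multiplies the
    automatic coordinates before comparison (e.g. ``(2, 2, 1)`` when
    tracking ran on a 2x2-reduced grid and the gold standard is in original
    pixels).
    """
    a = _as_table(auto).copy()
    g = _as_table(gold)
    if len(a) == 0:
        raise ValueError("automatic track set is empty")
    if len(g) == 0:
        raise ValueError("gold standard is empty")
    sx, sy, sz = scale
    a["x"] = a["x"] * sx
    a["y"] = a["y"] * sy
    a["z"] = a["z"] * sz
    d_ag, grp_ag, un_a = _directed(a, g)
    d_ga, grp_ga, un_g = _directed(g, a)

    def per_track(d, grp):
        out = {}
        for gid in np.unique(grp):
            out[int(gid)] = float(d[grp == gid].mean())
        return out

    return TrackDistanceReport(
        d_ag=float(d_ag.mean()) if len(d_ag) else float("nan"),
        d_ga=float(d_ga.mean()) if len(d_ga) else float("nan"),
        d_ag_median=float(np.median(d_ag)) if len(d_ag) else float("nan"),
        d_ga_median=float(np.median(d_ga)) if len(d_ga) else float("nan"),
        unmatched_auto=un_a,
        unmatched_gold=un_g,
        per_track_auto=per_track(d_ag, grp_ag) if len(d_ag) else {},
        per_track_gold=per_track(d_ga, grp_ga) if len(d_ga) else {},
    )


def match_tracks_to_gold(trackset: TrackSet, gold: GoldStandard,
                         scale: tuple[float, float, float] = (1, 1, 1)) -> dict[int, int]:
    """Greedy one-to-one assignment of automatic tracks to gold cells.

    Pairs are ranked by mean time-matched centroid distance; each automatic
    track and each gold cell is used at most once.  Returns
    ``{track_id: cell_id}``; an injective mapping covering every gold cell
    indicates node-for-node recovery of the gold paths.
    """
    sx, sy, sz = scale
    pairs = []
    for tid in sorted(trackset.tracks):
        df = trackset.track_dataframe(tid)
        pos = df[["x", "y", "z"]].to_numpy(dtype=float) * np.array([sx, sy, sz])
        ts = df["t"].to_numpy()
        for cid in sorted(gold.table["cell_id"].unique()):
            gtrack = gold.cell_track(cid).set_index("t")
            common = [i for i, t in enumerate(ts) if t in gtrack.index]
            if not common:
                continue
            gpos = gtrack.loc[[ts[i] for i in common], ["x", "y", "z"]].to_numpy(dtype=float)
            d = float(np.linalg.norm(pos[common] - gpos, axis=1).mean())
            pairs.append((d, tid, int(cid)))
    pairs.sort()
    used_t, used_c, out = set(), set(), {}
    for d, tid, cid in pairs:
        if tid in used_t or cid in used_c:
            continue
        used_t.add(tid)
        used_c.add(cid)
        out[tid] = cid
    return out


@dataclass
class SweepResult:
    """D_AG/D_GA as a function of the threshold rescaling fraction."""

    fractions: list[float]
    d_ag: list[float]
    d_ga: list[float]
    n_tracks: list[int]
    failures: dict[float, str] = field(default_factory=dict)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction": self.fractions, "d_ag": self.d_ag, "d_ga": self.d_ga,
             "n_tracks": self.n_tracks}
        )


def threshold_sweep(seq, gold: GoldStandard, fractions=None, config=None) -> SweepResult:
    """Robustness of the full pipeline to the threshold rescaling fraction.

    Runs segment + track end to end per fraction (default 0.4-1.4 in steps
    of 0.1) and reports D_AG/D_GA; a failure at one fraction is recorded and
    the sweep continues.
    """
    from .pipeline import PipelineConfig, run_pipeline

    if fractions is None:
        fractions = [round(0.4 + 0.1 * i, 1) for i in range(11)]
    fractions = sorted(float(f) for f in fractions)
    if any(f1 <= f0 for f0, f1 in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be strictly increasing")
    config = config or PipelineConfig()
    scale = (1.0, 1.0, 1.0)
    if config.reduce and hasattr(seq, "stacks"):
        # reduce once up front rather than inside every per-fraction run
        from .volume_io import reduce_sequence

        seq = reduce_sequence(seq)
        config = config.with_updates(reduce=False)
        scale = (2.0, 2.0, 1.0)
    out = SweepResult([], [], [], [])
    for f in fractions:
        cfg = config.with_updates(threshold_fraction=f)
        try:
            bundle = run_pipeline(seq, cfg)
            report = track_set_distance(bundle.trackset, gold, scale=scale)
            out.fractions.append(f)
            out.d_ag.append(report.d_ag)
            out.d_ga.append(report.d_ga)
            out.n_tracks.append(bundle.trackset.n_tracks)
        except Exception as exc:  # keep sweeping; record the failure
            out.fractions.append(f)
            out.d_ag.append(float("nan"))
            out.d_ga.append(float("nan"))
            out.n_tracks.append(0)
            out.failures[f] = f"{type(exc).__name__}: {exc}"
    return out
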