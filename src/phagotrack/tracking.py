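"""Keyhole-model tracking of segmented objects across time points.

A cell that moved from time t-1 ("grandparent" position) to t ("parent") is
most likely to continue with the same velocity, so its landing position at
t+1 ("child") can be predicted.  The region of probable landing is a keyhole:
a narrow wedge (60 deg wide by default) aimed at the constant-velocity
prediction for straight-moving cells, plus a complementary truncated sphere
(300 deg) around the current position for random-walk-like moves.  Both
scale with the previous displacement.  Candidate links are those falling
inside the keyhole; ambiguities are resolved greedily by distance to the
predicted landing point.

Post-processing raises track reliability: backward validation re-tests links
with a keyhole built from the two later points aimed backward in time; gap
bridging interpolates cells that blink out for a single frame; collision
resolution detects volume jumps coinciding with a neighbouring track's end
and re-splits the merged object by seeded watershed.  Delete/break/merge
editing operations with an audit log support manual proofreading.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import watershed

from .segmentation import LabeledStack, RegionRecord, _records_from_labels, _structure

NODE_COLUMNS = [
    "node_id", "t", "x", "y", "z", "volume", "mean_intensity",
    "frame_label", "parent_id", "child_id", "track_id", "interpolated",
]


@dataclass
class KeyholeParams:
    """Geometry and post-processing tunables of the keyhole tracker.

    The wedge and truncated-sphere sector angles must sum to 360 degrees.
    ``wedge_reach`` and ``circle_radius`` are multipliers of the previous
    displacement magnitude.  ``first_link_radius`` and ``gap_roi_radius``
    default (None) to 3x and 2x the median object diameter estimated from
    node volumes.  ``min_radius`` (default: 1x the median object diameter)
    is a floor on the keyhole extent: segmentation centroids jitter by a
    fraction of the cell size, so a keyhole smaller than that uncertainty
    would reject genuine links of slow, smoothly moving cells.
    ``idle_tolerance`` is the displacement (pixels) below which a cell
    counts as idle and the plain first-link sphere replaces the keyhole.
    ``use_2d`` evaluates keyhole geometry on (x, y) only, for strongly
    anisotropic z sampling.
    """

    wedge_angle: float = 60.0
    circle_angle: float = 300.0
    wedge_reach: float = 3.0
    circle_radius: float = 1.0
    first_link_radius: float | None = None
    gap_roi_radius: float | None = None
    min_radius: float | None = None
    collision_volume_ratio: float = 1.5
    idle_tolerance: float = 0.5
    max_gap: int = 1
    use_2d: bool = False
    backward_first_link_only: bool = False

    def __post_init__(self) -> None:
        if abs(self.wedge_angle + self.circle_angle - 360.0) > 1e-9:
            raise ValueError("wedge_angle + circle_angle must equal 360 degrees")
        if self.wedge_reach <= 0 or self.circle_radius <= 0:
            raise ValueError("keyhole multipliers must be > 0")

    def resolved(self, nodes: pd.DataFrame) -> "KeyholeParams":
        """Fill data-dependent defaults from the node table."""
        if (self.first_link_radius is not None and self.gap_roi_radius is not None
                and self.min_radius is not None):
            return self
        d_med = median_object_diameter(nodes)
        return replace(
            self,
            first_link_radius=self.first_link_radius if self.first_link_radius is not None else 3 * d_med,
            gap_roi_radius=self.gap_roi_radius if self.gap_roi_radius is not None else 2 * d_med,
            min_radius=self.min_radius if self.min_radius is not None else d_med,
        )


def median_object_diameter(nodes: pd.DataFrame) -> float:
    """Median equivalent-sphere diameter of the segmented objects."""
    vols = nodes["volume"].to_numpy(dtype=float)
    vols = vols[vols > 0]
    if len(vols) == 0:
        return 1.0
    return float(np.median(2.0 * np.cbrt(3.0 * vols / (4.0 * math.pi))))


def nodes_from_segmentation(
    labeled_seq: Sequence[tuple[LabeledStack, list[RegionRecord]]],
) -> pd.DataFrame:
    """Build the node table (one row per segmented object) from labels."""
    rows = []
    nid = 0
    for lstack, recs in labeled_seq:
        for r in sorted(recs, key=lambda r: r.label):
            nid += 1
            rows.append(
                dict(
                    node_id=nid, t=int(lstack.time_index),
                    x=r.centroid[0], y=r.centroid[1], z=r.centroid[2],
                    volume=float(r.volume), mean_intensity=r.mean_intensity,
                    frame_label=int(r.label), parent_id=pd.NA, child_id=pd.NA,
                    track_id=pd.NA, interpolated=False,
                )
            )
    df = pd.DataFrame(rows, columns=NODE_COLUMNS)
    return _normalise_nodes(df)


def _normalise_nodes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in NODE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA if col in ("parent_id", "child_id", "track_id") else (
                False if col == "interpolated" else np.nan
            )
    for col in ("parent_id", "child_id", "track_id"):
        df[col] = df[col].astype("Int64")
    df["node_id"] = df["node_id"].astype(int)
    df["t"] = df["t"].astype(int)
    df["interpolated"] = df["interpolated"].astype(bool)
    return df[NODE_COLUMNS].sort_values(["t", "node_id"], kind="stable").reset_index(drop=True)


class TrackSet:
    """A node table plus its partition into tracks.

    ``tracks`` maps track id to the ordered (by t) list of node ids; the node
    table mirrors membership in its ``track_id``/``parent_id``/``child_id``
    columns.  Edits append to ``audit_log``.
    """

    def __init__(self, nodes: pd.DataFrame, tracks: dict[int, list[int]],
                 audit_log: list | None = None, events: list | None = None):
        self.nodes = _normalise_nodes(nodes)
        self.tracks = {int(k): list(v) for k, v in tracks.items()}
        self.audit_log = audit_log if audit_log is not None else []
        self.events = events if events is not None else []
        self._sync_columns()

    def _sync_columns(self) -> None:
        idx = self.nodes.set_index("node_id").index
        track_of = {}
        parent = {}
        child = {}
        for tid, members in self.tracks.items():
            for i, nid in enumerate(members):
                track_of[nid] = tid
                if i > 0:
                    parent[nid] = members[i - 1]
                    child[members[i - 1]] = nid
        self.nodes["track_id"] = pd.array([track_of.get(n, pd.NA) for n in self.nodes["node_id"]], dtype="Int64")
        self.nodes["parent_id"] = pd.array([parent.get(n, pd.NA) for n in self.nodes["node_id"]], dtype="Int64")
        self.nodes["child_id"] = pd.array([child.get(n, pd.NA) for n in self.nodes["node_id"]], dtype="Int64")
        assert len(idx) == len(set(idx)), "duplicate node ids"

    # -- convenience -------------------------------------------------------
    def node(self, node_id: int) -> pd.Series:
        return self.nodes.loc[self.nodes["node_id"] == node_id].iloc[0]

    def positions(self, node_ids: Iterable[int]) -> np.ndarray:
        sub = self.nodes.set_index("node_id").loc[list(node_ids)]
        return sub[["x", "y", "z"]].to_numpy(dtype=float)

    def track_times(self, track_id: int) -> tuple[int, int]:
        sub = self.nodes.set_index("node_id").loc[self.tracks[track_id]]
        return int(sub["t"].min()), int(sub["t"].max())

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    def track_dataframe(self, track_id: int) -> pd.DataFrame:
        sub = self.nodes.set_index("node_id").loc[self.tracks[track_id]].reset_index()
        return sub

    def to_json(self) -> str:
        return json.dumps(
            {
                "tracks": {str(k): v for k, v in sorted(self.tracks.items())},
                "audit_log": self.audit_log,
            },
            indent=1,
        )


def _vec(p, use_2d: bool) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if use_2d:
        v = v[:2]
    elif v.shape[0] == 2:
        v = np.array([v[0], v[1], 0.0])
    return v


def keyhole_contains(
    params: KeyholeParams,
    grandparent,
    parent,
    candidate,
) -> tuple[bool, float]:
    """Test whether ``candidate`` lies inside the keyhole of a moving object.

    With history (grandparent at t-1, parent at t) the predicted landing is
    ``parent + (parent - grandparent)``; the candidate is inside when it
    falls either in the wedge (half-angle ``wedge_angle/2`` about the
    predicted direction, range ``wedge_reach`` x previous displacement from
    the parent) or in the complementary truncated sphere (radius
    ``circle_radius`` x previous displacement, outside the wedge sector).
    Without history, or when the previous displacement is below
    ``idle_tolerance``, a plain sphere of ``first_link_radius`` applies.

    Returns ``(inside, distance to the predicted landing point)``.
    """
    p = _vec(parent, params.use_2d)
    c = _vec(candidate, params.use_2d)
    gp = None if grandparent is None else _vec(grandparent, params.use_2d)
    if gp is not None:
        v = p - gp
        d = float(np.linalg.norm(v))
    else:
        d = 0.0
    if gp is None or d < params.idle_tolerance:
        if params.first_link_radius is None:
            raise ValueError("first_link_radius unresolved; call params.resolved(nodes) first")
        dist = float(np.linalg.norm(c - p))
        return dist <= params.first_link_radius, dist
    predicted = p + v
    off = c - p
    r = float(np.linalg.norm(off))
    dist = float(np.linalg.norm(c - predicted))
    if r == 0.0:
        return True, dist  # candidate sits on the parent: inside the sphere part
    cosang = float(np.dot(off, v) / (r * d))
    cosang = max(-1.0, min(1.0, cosang))
    ang = math.degrees(math.acos(cosang))
    floor = params.min_radius or 0.0
    if ang <= params.wedge_angle / 2.0:
        inside = r <= max(params.wedge_reach * d, floor)
    else:
        inside = r <= max(params.circle_radius * d, floor)
    return inside, dist


def link_sequence(nodes: pd.DataFrame, params: KeyholeParams | None = None) -> TrackSet:
    """Forward frame-by-frame linking of the node table into tracks.

    For every pair of consecutive time points, all (parent tail, next-frame
    candidate) pairs whose candidate falls inside the parent's keyhole are
    ranked by distance to the predicted landing point and assigned greedily,
    each node used at most once (ties broken by node id, so linking is
    deterministic).  Unassigned candidates open new tracks; parents with no
    assigned child close theirs.
    """
    params = (params or KeyholeParams()).resolved(nodes)
    nodes = _normalise_nodes(nodes)
    pos = {int(r.node_id): np.array([r.x, r.y, r.z]) for r in nodes.itertuples()}
    frames: dict[int, list[int]] = {}
    for r in nodes.itertuples():
        frames.setdefault(int(r.t), []).append(int(r.node_id))
    tracks: dict[int, list[int]] = {}
    track_of: dict[int, int] = {}
    next_tid = 1
    ts = sorted(frames)
    for i, t in enumerate(ts):
        assigned: set[int] = set()
        if i > 0 and ts[i - 1] == t - 1:
            parents = [n for n in frames[ts[i - 1]]]
            pairs = []
            for p_nid in parents:
                tid = track_of[p_nid]
                members = tracks[tid]
                if members[-1] != p_nid:
                    continue
                gp = pos[members[-2]] if len(members) >= 2 else None
                for c_nid in frames[t]:
                    inside, dist = keyhole_contains(params, gp, pos[p_nid], pos[c_nid])
                    if inside:
                        pairs.append((dist, p_nid, c_nid))
            pairs.sort()
            used_parents: set[int] = set()
            for dist, p_nid, c_nid in pairs:
                if p_nid in used_parents or c_nid in assigned:
                    continue
                used_parents.add(p_nid)
                assigned.add(c_nid)
                tid = track_of[p_nid]
                tracks[tid].append(c_nid)
                track_of[c_nid] = tid
        for c_nid in frames[t]:
            if c_nid not in assigned and c_nid not in track_of:
                tracks[next_tid] = [c_nid]
                track_of[c_nid] = next_tid
                next_tid += 1
    return TrackSet(nodes, tracks)


def backward_validate(trackset: TrackSet, params: KeyholeParams | None = None) -> TrackSet:
    """Re-test links with the keyhole built backward in time.

    For a link between nodes at t and t+1, the keyhole is generated from the
    grandchild (t+2) and child (t+1) pointing backward; if the t node falls
    outside, the link is cut and the head segment becomes its own track (for
    the first link of a track this turns a spurious first node into a
    singleton).  Tracks shorter than 3 nodes are untouched.  With
    ``backward_first_link_only`` only each track's first link is tested,
    which is where validation matters most (no prior motion history).
    """
    params = (params or KeyholeParams()).resolved(trackset.nodes)
    pos = {int(r.node_id): np.array([r.x, r.y, r.z]) for r in trackset.nodes.itertuples()}
    new_tracks: dict[int, list[int]] = {}
    next_tid = 1
    for tid in sorted(trackset.tracks):
        members = trackset.tracks[tid]
        if len(members) < 3:
            new_tracks[next_tid] = members
            next_tid += 1
            continue
        cuts = []
        link_range = [0] if params.backward_first_link_only else range(len(members) - 2)
        for i in link_range:
            n0, n1, n2 = members[i], members[i + 1], members[i + 2]
            inside, _ = keyhole_contains(params, pos[n2], pos[n1], pos[n0])
            if not inside:
                cuts.append(i)
        segments = []
        start = 0
        for c in cuts:
            segments.append(members[start : c + 1])
            start = c + 1
        segments.append(members[start:])
        for seg in segments:
            if seg:
                new_tracks[next_tid] = seg
                next_tid += 1
    return TrackSet(trackset.nodes, new_tracks, trackset.audit_log, trackset.events)


def bridge_gaps(trackset: TrackSet, params: KeyholeParams | None = None) -> TrackSet:
    """Bridge single-frame disappearances by interpolation.

    A cell present at t-1, absent at t and present again at t+1 within a
    small region of interest is taken to be a faint cell that dipped below
    the detection threshold: an artificial node is inserted at t (midpoint
    centroid, mean volume, ``interpolated=True``) and the two track fragments
    are merged.  When several candidates compete, the nearest endpoint wins;
    ties go to the lower track id (logged).  Gaps longer than
    ``params.max_gap`` frames are never bridged.
    """
    params = (params or KeyholeParams()).resolved(trackset.nodes)
    nodes = trackset.nodes.copy()
    tracks = {k: list(v) for k, v in trackset.tracks.items()}
    audit = list(trackset.audit_log)
    events = list(trackset.events)
    next_node_id = int(nodes["node_id"].max()) + 1 if len(nodes) else 1

    changed = True
    while changed:
        changed = False
        info = nodes.set_index("node_id")
        ends = {tid: m[-1] for tid, m in tracks.items()}
        starts = {tid: m[0] for tid, m in tracks.items()}
        candidates = []
        for tid_a, end_nid in ends.items():
            t_end = int(info.loc[end_nid, "t"])
            pa = info.loc[end_nid, ["x", "y", "z"]].to_numpy(dtype=float)
            for tid_b, start_nid in starts.items():
                if tid_b == tid_a:
                    continue
                t_start = int(info.loc[start_nid, "t"])
                gap = t_start - t_end - 1
                if not (1 <= gap <= params.max_gap):
                    continue
                pb = info.loc[start_nid, ["x", "y", "z"]].to_numpy(dtype=float)
                dist = float(np.linalg.norm(pb - pa))
                if dist <= params.gap_roi_radius:
                    candidates.append((dist, tid_a, tid_b))
        candidates.sort()
        used: set[int] = set()
        for dist, tid_a, tid_b in candidates:
            if tid_a in used or tid_b in used:
                continue
            used.update((tid_a, tid_b))
            end_nid, start_nid = tracks[tid_a][-1], tracks[tid_b][0]
            a = info.loc[end_nid]
            b = info.loc[start_nid]
            mid_t = int(a["t"]) + 1
            new_row = dict(
                node_id=next_node_id, t=mid_t,
                x=(a["x"] + b["x"]) / 2, y=(a["y"] + b["y"]) / 2, z=(a["z"] + b["z"]) / 2,
                volume=(a["volume"] + b["volume"]) / 2,
                mean_intensity=(a["mean_intensity"] + b["mean_intensity"]) / 2,
                frame_label=0, parent_id=pd.NA, child_id=pd.NA, track_id=pd.NA,
                interpolated=True,
            )
            nodes = pd.concat([nodes, _normalise_nodes(pd.DataFrame([new_row]))],
                              ignore_index=True)
            tracks[tid_a] = tracks[tid_a] + [next_node_id] + tracks[tid_b]
            audit.append({"action": "bridge_gap", "track": tid_a, "merged_track": tid_b,
                          "t": mid_t, "node_id": next_node_id, "distance": dist})
            del tracks[tid_b]
            next_node_id += 1
            changed = True
    # renumber tracks consecutively for stable output
    renum = {old: new for new, old in enumerate(sorted(tracks), start=1)}
    tracks = {renum[old]: m for old, m in tracks.items()}
    return TrackSet(nodes, tracks, audit, events)


def _watershed_split(
    labels: np.ndarray,
    target_label: int,
    seeds_xyz: Sequence[np.ndarray],
    connectivity: int,
) -> np.ndarray | None:
    """Split one labelled object by watershed on the inverted EDT.

    Markers are the seed points snapped to the nearest in-object voxel.  A
    compact watershed (compactness 0.5) is used: on a dumbbell-shaped merge
    the cut still falls on the EDT neck, while on heavily overlapping
    near-spherical cells — whose inverted EDT has a single central minimum
    and no ridge — the compactness term regularises the partition toward
    the nearest-seed (Voronoi) split instead of letting one basin flood the
    whole object.  Returns a per-voxel seed-index array (1..n_seeds over
    the object) or None when the watershed yields fewer regions than seeds.
    """
    mask = labels == target_label
    if not mask.any():
        return None
    edt = ndimage.distance_transform_edt(mask)
    markers = np.zeros(labels.shape, dtype=np.int32)
    # snap each seed to the nearest voxel of the object
    _, nearest = ndimage.distance_transform_edt(~mask, return_indices=True)
    for i, s in enumerate(seeds_xyz, start=1):
        y = int(round(s[1])); x = int(round(s[0])); z = int(round(s[2]))
        y = min(max(y, 0), labels.shape[0] - 1)
        x = min(max(x, 0), labels.shape[1] - 1)
        z = min(max(z, 0), labels.shape[2] - 1)
        if not mask[y, x, z]:
            y, x, z = (int(nearest[0][y, x, z]), int(nearest[1][y, x, z]), int(nearest[2][y, x, z]))
        markers[y, x, z] = i
    if len(np.unique(markers)) - 1 < len(seeds_xyz):
        return None  # two seeds snapped to the same voxel
    parts = watershed(-edt, markers=markers, mask=mask,
                      connectivity=_structure(connectivity), compactness=0.5)
    if len(np.unique(parts)) - 1 < len(seeds_xyz):
        return None
    return parts


def resolve_collisions(
    trackset: TrackSet,
    labeled_seq: list[tuple[LabeledStack, list[RegionRecord]]],
    params: KeyholeParams | None = None,
    intensity_stacks=None,
    connectivity: int = 26,
) -> tuple[TrackSet, list[tuple[LabeledStack, list[RegionRecord]]]]:
    """Detect collisions, re-split merged objects, and re-track.

    A merge is flagged when a track's volume jumps by at least
    ``collision_volume_ratio`` from one frame to the next AND another track
    terminates at the previous frame within ``gap_roi_radius`` (two cells
    close enough merge into one segmented object).  The merged object is
    re-split frame by frame with a watershed on its inverted distance
    transform, seeded at the colliding tracks' previous centroids; total
    foreground volume is conserved because the watershed partitions the
    object's own voxels.  Division events (the inverse signature: a volume
    drop together with a track birth nearby) are detected and logged.  After
    any split, linking, backward validation and gap bridging are re-run on
    the updated node table.

    Merged cells can separate and re-merge repeatedly while crossing, so the
    procedure iterates: detect the earliest unhandled merge, split its
    merged frames, rebuild the node table and re-track, until no new merge
    is detected (or an iteration cap is hit).

    Returns the new track set and the (possibly modified) labelled sequence.
    """
    params = (params or KeyholeParams()).resolved(trackset.nodes)
    stacks_by_t = {ls.time_index: (ls, recs) for ls, recs in labeled_seq}
    events = list(trackset.events)
    audit = list(trackset.audit_log)
    failed: set[tuple[int, int]] = set()  # (t, frame_label) watershed failures
    ts = trackset

    for _ in range(50):
        info = ts.nodes.set_index("node_id")
        merge_events = _detect_merge_events(ts, params, info, skip=failed)
        if not merge_events:
            break
        ev = min(merge_events, key=lambda e: (e["t"], e["track"]))
        tid, t0, other_tid = ev["track"], ev["t"], ev["terminated_track"]
        members = ts.tracks[tid]
        t_of = {nid: int(info.loc[nid, "t"]) for nid in members}
        prev_nid = next(n for n in members if t_of[n] == t0 - 1)
        other_last = ts.tracks[other_tid][-1]
        seeds = [
            info.loc[prev_nid, ["x", "y", "z"]].to_numpy(dtype=float),
            info.loc[other_last, ["x", "y", "z"]].to_numpy(dtype=float),
        ]
        v_ref = float(info.loc[prev_nid, "volume"])
        touched = False
        t = t0
        while True:  # walk forward while the track's object still looks merged
            here = [n for n in members if t_of.get(n) == t]
            if not here:
                break
            nid = here[0]
            if float(info.loc[nid, "volume"]) < params.collision_volume_ratio * v_ref:
                break
            label = int(info.loc[nid, "frame_label"])
            if label == 0 or t not in stacks_by_t:
                break  # interpolated node: nothing to re-split
            lstack, _ = stacks_by_t[t]
            parts = _watershed_split(lstack.labels, label, seeds, connectivity)
            if parts is None:
                events.append({"event": "merge_unsplit", "track": tid, "t": t, "label": label})
                failed.add((t, label))
                break
            new_labels = lstack.labels.copy()
            base = int(new_labels.max())
            for i in range(1, len(seeds) + 1):
                new_labels[parts == i] = base + i
            intens = None
            if intensity_stacks is not None:
                intens = (intensity_stacks[t] if isinstance(intensity_stacks, dict)
                          else intensity_stacks[t].intensities)
            from .segmentation import _compact_labels
            compacted, _ = _compact_labels(new_labels)
            new_stack = LabeledStack(compacted, time_index=t)
            new_recs = _records_from_labels(new_stack, intens)
            stacks_by_t[t] = (new_stack, new_recs)
            touched = True
            events.append({"event": "merge_split", "track": tid, "other_track": other_tid,
                           "t": t, "n_seeds": len(seeds)})
            piece_centroids = []
            for i in range(1, len(seeds) + 1):
                ys, xs, zs = np.nonzero(parts == i)
                piece_centroids.append(np.array([xs.mean(), ys.mean(), zs.mean()]))
            seeds = piece_centroids
            t += 1
        if not touched:
            failed.add((t0, int(info.loc[next(n for n in members if t_of[n] == t0), "frame_label"])))
            continue
        new_labeled = [stacks_by_t[t_] for t_ in sorted(stacks_by_t)]
        new_nodes = nodes_from_segmentation(new_labeled)
        ts = link_sequence(new_nodes, params)
        ts = backward_validate(ts, params)
        ts = bridge_gaps(ts, params)

    new_labeled = [stacks_by_t[t_] for t_ in sorted(stacks_by_t)]
    ts = TrackSet(ts.nodes, ts.tracks, audit + ts.audit_log, events)
    ts.events.extend(_detect_division_events(ts, params))
    return ts, new_labeled


def _detect_merge_events(trackset: TrackSet, params: KeyholeParams,
                         info: pd.DataFrame | None = None,
                         skip: set | None = None) -> list[dict]:
    if info is None:
        info = trackset.nodes.set_index("node_id")
    skip = skip or set()
    track_ends = {tid: m[-1] for tid, m in trackset.tracks.items()}
    out = []
    for tid in sorted(trackset.tracks):
        members = trackset.tracks[tid]
        for prev_nid, nid in zip(members, members[1:]):
            v0 = float(info.loc[prev_nid, "volume"])
            v1 = float(info.loc[nid, "volume"])
            t = int(info.loc[nid, "t"])
            if v0 <= 0 or v1 < params.collision_volume_ratio * v0:
                continue
            if (t, int(info.loc[nid, "frame_label"])) in skip:
                continue
            p = info.loc[nid, ["x", "y", "z"]].to_numpy(dtype=float)
            for other_tid, end_nid in sorted(track_ends.items()):
                if other_tid == tid:
                    continue
                if int(info.loc[end_nid, "t"]) != t - 1:
                    continue
                q = info.loc[end_nid, ["x", "y", "z"]].to_numpy(dtype=float)
                if float(np.linalg.norm(p - q)) <= params.gap_roi_radius:
                    out.append({"event": "merge", "track": tid, "t": t,
                                "terminated_track": other_tid})
                    break
            else:
                continue
            break  # handle one merge per track per pass
    return out


def _detect_division_events(trackset: TrackSet, params: KeyholeParams) -> list[dict]:
    """Inverse signature of a merge: volume drop plus a track birth nearby."""
    info = trackset.nodes.set_index("node_id")
    track_starts = {tid: m[0] for tid, m in trackset.tracks.items()}
    out = []
    for tid in sorted(trackset.tracks):
        members = trackset.tracks[tid]
        for prev_nid, nid in zip(members, members[1:]):
            v0 = float(info.loc[prev_nid, "volume"])
            v1 = float(info.loc[nid, "volume"])
            t = int(info.loc[nid, "t"])
            if v1 <= 0 or v0 < params.collision_volume_ratio * v1:
                continue
            p = info.loc[nid, ["x", "y", "z"]].to_numpy(dtype=float)
            for other_tid, start_nid in sorted(track_starts.items()):
                if other_tid == tid or int(info.loc[start_nid, "t"]) != t:
                    continue
                q = info.loc[start_nid, ["x", "y", "z"]].to_numpy(dtype=float)
                if float(np.linalg.norm(p - q)) <= params.gap_roi_radius:
                    out.append({"event": "division", "track": tid, "t": t,
                                "new_track": other_tid})
                    break
    return out


def edit_tracks(trackset: TrackSet, action: str, **kwargs) -> TrackSet:
    """Programmatic proofreading edits: ``delete``, ``break`` or ``merge``.

    delete(track)
        Remove the track; its nodes become unassigned.
    break(track, at)
        Split one track into two at time ``at`` (the node at ``at`` starts
        the second track); breaking at an endpoint is an error.
    merge(track_a, track_b)
        Concatenate two temporally disjoint tracks (a must end before b
        starts); a single-frame gap is bridged by interpolation.

    Every edit is appended to the audit log.
    """
    tracks = {k: list(v) for k, v in trackset.tracks.items()}
    nodes = trackset.nodes
    audit = list(trackset.audit_log)
    info = nodes.set_index("node_id")

    if action == "delete":
        tid = int(kwargs["track"])
        if tid not in tracks:
            raise KeyError(f"track {tid} does not exist")
        del tracks[tid]
        audit.append({"action": "delete", "track": tid})
    elif action == "break":
        tid = int(kwargs["track"])
        at = int(kwargs["at"])
        if tid not in tracks:
            raise KeyError(f"track {tid} does not exist")
        members = tracks[tid]
        times = [int(info.loc[n, "t"]) for n in members]
        if at not in times:
            raise ValueError(f"track {tid} has no node at t={at}")
        i = times.index(at)
        if i == 0 or i == len(members) - 1:
            raise ValueError("cannot break a track at its endpoint")
        new_tid = max(tracks) + 1
        tracks[tid] = members[:i]
        tracks[new_tid] = members[i:]
        audit.append({"action": "break", "track": tid, "at": at, "new_track": new_tid})
    elif action == "merge":
        ta, tb = int(kwargs["track_a"]), int(kwargs["track_b"])
        for t_ in (ta, tb):
            if t_ not in tracks:
                raise KeyError(f"track {t_} does not exist")
        end_a = int(info.loc[tracks[ta][-1], "t"])
        start_b = int(info.loc[tracks[tb][0], "t"])
        if start_b <= end_a:
            raise ValueError(
                f"cannot merge temporally overlapping tracks (track {ta} ends at "
                f"{end_a}, track {tb} starts at {start_b})"
            )
        gap = start_b - end_a - 1
        if gap > 1:
            raise ValueError(f"gap of {gap} frames between tracks {ta} and {tb}; at most 1 is bridged")
        if gap == 1:
            a = info.loc[tracks[ta][-1]]
            b = info.loc[tracks[tb][0]]
            new_nid = int(nodes["node_id"].max()) + 1
            row = dict(node_id=new_nid, t=end_a + 1,
                       x=(a["x"] + b["x"]) / 2, y=(a["y"] + b["y"]) / 2, z=(a["z"] + b["z"]) / 2,
                       volume=(a["volume"] + b["volume"]) / 2,
                       mean_intensity=(a["mean_intensity"] + b["mean_intensity"]) / 2,
                       frame_label=0, parent_id=pd.NA, child_id=pd.NA, track_id=pd.NA,
                       interpolated=True)
            nodes = pd.concat([nodes, _normalise_nodes(pd.DataFrame([row]))],
                              ignore_index=True)
            tracks[ta] = tracks[ta] + [new_nid] + tracks[tb]
        else:
            tracks[ta] = tracks[ta] + tracks[tb]
        del tracks[tb]
        audit.append({"action": "merge", "track_a": ta, "track_b": tb})
    else:
        raise ValueError(f"unknown edit action {action!r}; expected delete, break or merge")
    return TrackSet(nodes, tracks, audit, list(trackset.events))
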