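"""Keyhole geometry, linking, post-processing and editing."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phagotrack.segmentation import label_regions
from phagotrack.tracking import (
    KeyholeParams, keyhole_contains, link_sequence, backward_validate,
    bridge_gaps, resolve_collisions, edit_tracks, nodes_from_segmentation,
)

from conftest import make_nodes, make_trackset


RAW = KeyholeParams(first_link_radius=3.0)  # pure spec geometry, no data floor


def keyhole_oracle(params, gp, p, c):
    """Independent geometric classification via an explicit local frame."""
    gp, p, c = (np.asarray(v, float) for v in (gp, p, c))
    v = p - gp
    d = np.linalg.norm(v)
    if d < params.idle_tolerance:
        return np.linalg.norm(c - p) <= params.first_link_radius
    off = c - p
    r = np.linalg.norm(off)
    if r == 0:
        return True
    # angle via atan2 of (parallel, perpendicular) components in local frame
    par = np.dot(off, v / d)
    perp = math.sqrt(max(r ** 2 - par ** 2, 0.0))
    ang = math.degrees(math.atan2(perp, par))
    floor = params.min_radius or 0.0
    if ang <= params.wedge_angle / 2:
        return r <= max(params.wedge_reach * d, floor)
    return r <= max(params.circle_radius * d, floor)


class TestKeyholeContains:
    def test_straight_continuation_dead_centre(self):
        inside, dist = keyhole_contains(RAW, (0, 0, 0), (1, 0, 0), (2, 0, 0))
        assert inside and dist == pytest.approx(0.0)

    def test_lateral_candidate_in_truncated_sphere(self):
        inside, _ = keyhole_contains(RAW, (0, 0, 0), (1, 0, 0), (1, 0.5, 0))
        assert inside  # 90 deg off-axis, |offset| 0.5 <= circle radius 1

    def test_beyond_wedge_reach_outside(self):
        inside, _ = keyhole_contains(RAW, (0, 0, 0), (1, 0, 0), (10, 0, 0))
        assert not inside  # 9 > wedge_reach * d = 3

    def test_first_link_sphere_without_history(self):
        inside, dist = keyhole_contains(RAW, None, (0, 0, 0), (2, 2, 0))
        assert inside and dist == pytest.approx(math.sqrt(8))
        assert not keyhole_contains(RAW, None, (0, 0, 0), (3, 3, 0))[0]

    def test_idle_parent_uses_first_link_sphere(self):
        inside, _ = keyhole_contains(RAW, (0, 0, 0), (0.1, 0, 0), (2, 1, 0))
        assert inside  # displacement 0.1 < idle tolerance

    def test_wedge_and_sphere_sectors_are_complementary(self):
        assert RAW.wedge_angle + RAW.circle_angle == 360.0
        with pytest.raises(ValueError):
            KeyholeParams(wedge_angle=90.0)

    def test_monte_carlo_matches_geometry_oracle(self):
        rng = np.random.default_rng(7)
        params = KeyholeParams(first_link_radius=3.0, idle_tolerance=0.5)
        mismatches = 0
        for _ in range(10_000):
            gp = rng.uniform(-5, 5, 3)
            p = gp + rng.uniform(-3, 3, 3)
            c = p + rng.uniform(-6, 6, 3)
            got, _ = keyhole_contains(params, gp, p, c)
            assert got == keyhole_oracle(params, gp, p, c)
        assert mismatches == 0


def straight_nodes(n_frames, start, step, t0=0):
    pts = [(t0 + i,
            start[0] + i * step[0], start[1] + i * step[1], start[2] + i * step[2])
           for i in range(n_frames)]
    return pts


class TestLinkSequence:
    def test_single_moving_object_single_track(self):
        nodes = make_nodes(straight_nodes(10, (5, 5, 2), (2, 0, 0)))
        ts = link_sequence(nodes, KeyholeParams(first_link_radius=5, min_radius=0))
        assert ts.n_tracks == 1
        assert len(ts.tracks[1]) == 10

    def test_parallel_tracks_never_switch(self):
        pts = straight_nodes(10, (0, 0, 0), (2, 0, 0)) + straight_nodes(10, (0, 50, 0), (2, 0, 0))
        ts = link_sequence(make_nodes(pts), KeyholeParams(first_link_radius=5, min_radius=0))
        assert ts.n_tracks == 2
        ys = {tid: set(ts.track_dataframe(tid)["y"]) for tid in ts.tracks}
        assert any(v == {0.0} for v in ys.values())
        assert any(v == {50.0} for v in ys.values())

    def test_greedy_matches_exhaustive_assignment(self):
        rng = np.random.default_rng(8)
        params = KeyholeParams(first_link_radius=6.0, min_radius=0)
        for trial in range(5):
            n_obj = rng.integers(2, 5)
            starts = rng.uniform(0, 200, size=(n_obj, 3)) * np.array([1, 1, 0.05])
            steps = rng.uniform(-2, 2, size=(n_obj, 3)) * np.array([1, 1, 0.1])
            pts = []
            for k in range(n_obj):
                pts += straight_nodes(6, starts[k], steps[k])
            nodes = make_nodes(sorted(pts))
            ts = link_sequence(nodes, params)
            exhaustive = exhaustive_link(nodes, params)
            got = {tuple(sorted(m)) for m in ts.tracks.values()}
            assert got == exhaustive

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        pts = [(t, *rng.uniform(0, 100, 2), 0) for t in range(5) for _ in range(4)]
        nodes = make_nodes(pts)
        p = KeyholeParams(first_link_radius=30.0)
        a = link_sequence(nodes, p)
        b = link_sequence(nodes, p)
        assert a.tracks == b.tracks

    def test_every_link_satisfies_keyhole(self):
        rng = np.random.default_rng(10)
        pts = [(t, *rng.uniform(0, 60, 2), 0) for t in range(6) for _ in range(3)]
        nodes = make_nodes(pts)
        params = KeyholeParams(first_link_radius=25.0, min_radius=0).resolved(nodes)
        ts = link_sequence(nodes, params)
        info = ts.nodes.set_index("node_id")
        for members in ts.tracks.values():
            for i in range(1, len(members)):
                gp = None if i < 2 else info.loc[members[i - 2], ["x", "y", "z"]].to_numpy(float)
                p = info.loc[members[i - 1], ["x", "y", "z"]].to_numpy(float)
                c = info.loc[members[i], ["x", "y", "z"]].to_numpy(float)
                assert keyhole_contains(params, gp, p, c)[0]
        # no node in two tracks
        all_ids = [n for m in ts.tracks.values() for n in m]
        assert len(all_ids) == len(set(all_ids))


def exhaustive_link(nodes, params):
    """Frame-by-frame optimal assignment by brute-force enumeration.

    Minimises the total distance-to-prediction over all injective matchings
    of keyhole-admissible pairs, frame by frame (the greedy target on
    well-separated fixtures).
    """
    params = params.resolved(nodes)
    pos = {int(r.node_id): np.array([r.x, r.y, r.z]) for r in nodes.itertuples()}
    frames = {}
    for r in nodes.itertuples():
        frames.setdefault(int(r.t), []).append(int(r.node_id))
    tracks = {}
    track_of = {}
    next_tid = 1
    ts_sorted = sorted(frames)
    for i, t in enumerate(ts_sorted):
        assigned = set()
        if i > 0 and ts_sorted[i - 1] == t - 1:
            parents = [n for n in frames[ts_sorted[i - 1]]
                       if tracks[track_of[n]][-1] == n]
            cands = frames[t]
            admissible = {}
            for p_nid in parents:
                members = tracks[track_of[p_nid]]
                gp = pos[members[-2]] if len(members) >= 2 else None
                for c_nid in cands:
                    ok, dist = keyhole_contains(params, gp, pos[p_nid], pos[c_nid])
                    if ok:
                        admissible[(p_nid, c_nid)] = dist
            best, best_match = None, []
            for k in range(min(len(parents), len(cands)), -1, -1):
                for psub in itertools.combinations(parents, k):
                    for csub in itertools.permutations(cands, k):
                        pairs = list(zip(psub, csub))
                        if any(pr not in admissible for pr in pairs):
                            continue
                        cost = sum(admissible[pr] for pr in pairs)
                        if best is None or cost < best:
                            best, best_match = cost, pairs
                if best is not None:
                    break  # maximise cardinality first, then min cost
            for p_nid, c_nid in best_match:
                tid = track_of[p_nid]
                tracks[tid].append(c_nid)
                track_of[c_nid] = tid
                assigned.add(c_nid)
        for c_nid in frames[t]:
            if c_nid not in assigned and c_nid not in track_of:
                tracks[next_tid] = [c_nid]
                track_of[c_nid] = next_tid
                next_tid += 1
    return {tuple(sorted(m)) for m in tracks.values()}


class TestBackwardValidate:
    def test_straight_track_unchanged(self):
        ts = make_trackset({1: [(t, 2.0 * t, 5, 0) for t in range(8)]})
        out = backward_validate(ts, KeyholeParams(first_link_radius=5, min_radius=0))
        assert out.n_tracks == 1 and len(out.tracks[1]) == 8

    def test_spurious_first_node_removed(self):
        pts = [(0, 0, 20, 0)] + [(t, 10 + t, 0, 0) for t in range(1, 8)]
        ts = make_trackset({1: pts})
        out = backward_validate(ts, KeyholeParams(first_link_radius=3, min_radius=0))
        assert out.n_tracks == 2
        lengths = sorted(len(m) for m in out.tracks.values())
        assert lengths == [1, 7]

    def test_two_node_track_untouched(self):
        ts = make_trackset({1: [(0, 0, 0, 0), (1, 50, 50, 0)]})
        out = backward_validate(ts, KeyholeParams(first_link_radius=1, min_radius=0))
        assert out.n_tracks == 1 and len(out.tracks[1]) == 2


class TestBridgeGaps:
    def test_single_frame_gap_interpolated(self):
        ts = make_trackset({
            1: [(t, 2.0 * t, 0, 0) for t in range(0, 5)],       # t=0..4
            2: [(t, 2.0 * t, 0, 0) for t in range(6, 10)],      # t=6..9
        })
        out = bridge_gaps(ts, KeyholeParams(first_link_radius=5, gap_roi_radius=6))
        assert out.n_tracks == 1
        members = list(out.tracks.values())[0]
        df = out.nodes.set_index("node_id").loc[members]
        assert list(df["t"]) == list(range(10))
        interp = df[df["interpolated"]]
        assert len(interp) == 1
        assert interp["t"].iloc[0] == 5
        assert interp["x"].iloc[0] == pytest.approx((8 + 12) / 2)
        assert interp["volume"].iloc[0] == pytest.approx(100.0)

    def test_far_endpoints_stay_separate(self):
        ts = make_trackset({
            1: [(t, t, 0, 0) for t in range(0, 5)],
            2: [(t, 100 + t, 0, 0) for t in range(6, 10)],
        })
        out = bridge_gaps(ts, KeyholeParams(first_link_radius=5, gap_roi_radius=10))
        assert out.n_tracks == 2

    def test_blinking_cell_fully_bridged(self):
        # visible on even frames only; single-frame gaps throughout
        ts = make_trackset({t // 2 + 1: [(t, 2.0 * t, 0, 0)] for t in range(0, 12, 2)})
        out = bridge_gaps(ts, KeyholeParams(first_link_radius=5, gap_roi_radius=6))
        assert out.n_tracks == 1
        members = list(out.tracks.values())[0]
        assert len(members) == 11  # t = 0..10 inclusive

    def test_long_gap_not_bridged(self):
        ts = make_trackset({
            1: [(t, t, 0, 0) for t in range(0, 3)],
            2: [(t, t, 0, 0) for t in range(6, 9)],
        })
        out = bridge_gaps(ts, KeyholeParams(first_link_radius=5, gap_roi_radius=50))
        assert out.n_tracks == 2


def ball(shape, center, radius):
    yy, xx, zz = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 + (zz - center[2]) ** 2
            <= radius ** 2)


def colliding_sequence(n_t=9, shape=(30, 60, 12)):
    """Two spheres approach, overlap for 3 frames, then separate."""
    labeled = []
    for t in range(n_t):
        xa = 12 + 4 * t
        xb = 48 - 4 * t
        m = ball(shape, (15, xa, 6), 4) | ball(shape, (15, xb, 6), 4)
        labeled.append(label_regions(m, time_index=t))
    return labeled


class TestResolveCollisions:
    def test_collision_split_two_tracks_volume_conserved(self):
        labeled = colliding_sequence()
        before = [int(np.count_nonzero(ls.labels)) for ls, _ in labeled]
        nodes = nodes_from_segmentation(labeled)
        params = KeyholeParams(first_link_radius=8, gap_roi_radius=10, min_radius=5)
        ts = link_sequence(nodes, params)
        ts2, labeled2 = resolve_collisions(ts, labeled, params)
        after = [int(np.count_nonzero(ls.labels)) for ls, _ in labeled2]
        assert after == before  # foreground voxel count conserved per frame
        long_tracks = [m for m in ts2.tracks.values() if len(m) >= 8]
        assert len(long_tracks) == 2
        # split volumes sum to the merged volume in each formerly merged frame
        for ls, recs in labeled2:
            assert sum(r.volume for r in recs) == before[ls.time_index]

    def test_small_volume_step_no_event(self):
        ts = make_trackset({
            1: [(0, 0, 0, 0), (1, 2, 0, 0), (2, 4, 0, 0)],
        }).nodes
        ts = make_trackset({1: [(0, 0, 0, 0), (1, 2, 0, 0), (2, 4, 0, 0)]})
        # volumes constant -> 1.1x jump absent, and no terminating neighbour
        from phagotrack.tracking import _detect_merge_events
        assert _detect_merge_events(ts, KeyholeParams(first_link_radius=5,
                                                      gap_roi_radius=5, min_radius=0)) == []

    def test_division_event_logged_on_reversed_fixture(self):
        labeled = colliding_sequence()
        nodes = nodes_from_segmentation(labeled)
        params = KeyholeParams(first_link_radius=8, gap_roi_radius=10, min_radius=5)
        ts = link_sequence(nodes, params)
        ts2, _ = resolve_collisions(ts, labeled, params)
        kinds = {e["event"] for e in ts2.events}
        assert "merge_split" in kinds


class TestEditTracks:
    def make(self):
        return make_trackset({7: [(t, 2.0 * t, 0, 0) for t in range(10)]})

    def test_break_then_merge_restores(self):
        ts = self.make()
        broken = edit_tracks(ts, "break", track=7, at=5)
        assert sorted(len(m) for m in broken.tracks.values()) == [5, 5]
        new_tid = max(broken.tracks)
        merged = edit_tracks(broken, "merge", track_a=7, track_b=new_tid)
        assert merged.n_tracks == 1
        assert list(merged.tracks.values())[0] == list(ts.tracks.values())[0]
        assert len(merged.audit_log) == 2

    def test_break_at_endpoint_rejected(self):
        with pytest.raises(ValueError, match="endpoint"):
            edit_tracks(self.make(), "break", track=7, at=0)

    def test_merge_overlapping_rejected(self):
        ts = make_trackset({
            1: [(t, t, 0, 0) for t in range(5)],
            2: [(t, t, 10, 0) for t in range(3, 8)],
        })
        with pytest.raises(ValueError, match="overlap"):
            edit_tracks(ts, "merge", track_a=1, track_b=2)

    def test_merge_bridges_single_frame_gap(self):
        ts = make_trackset({
            1: [(t, t, 0, 0) for t in range(0, 4)],
            2: [(t, t, 0, 0) for t in range(5, 9)],
        })
        out = edit_tracks(ts, "merge", track_a=1, track_b=2)
        members = out.tracks[1]
        df = out.nodes.set_index("node_id").loc[members]
        assert list(df["t"]) == list(range(9))
        assert df["interpolated"].sum() == 1

    def test_delete_excludes_nodes_from_metrics(self):
        from phagotrack.kinematics import build_wound_frame, population_metrics
        ts = make_trackset({
            1: [(t, 10.0 + t, 10, 0) for t in range(5)],
            2: [(t, 10.0 + t, 40, 0) for t in range(5)],
        })
        frame = build_wound_frame((80, 100, 0, 50), wound_side="right")
        full = population_metrics(ts, frame)
        deleted = edit_tracks(ts, "delete", track=2)
        part = population_metrics(deleted, frame)
        assert full["n_tracks"] == 2 and part["n_tracks"] == 1
        assert part["n_displacements"] == full["n_displacements"] // 2
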