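"""Wound frame, displacement decomposition, track/population metrics, bands."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phagotrack.kinematics import (
    WoundFrame, build_wound_frame, displacement_components, track_metrics,
    population_metrics, volume_position_profile,
)

from conftest import make_trackset

RECT = (80.0, 100.0, 0.0, 100.0)


class TestWoundFrame:
    def test_right_edge_axes(self):
        f = build_wound_frame(RECT, (100, 100), "right")
        assert f.c_axis == (1.0, 0.0)
        assert f.r_axis == (0.0, 1.0)

    def test_top_edge_axes(self):
        f = build_wound_frame((0, 100, 0, 20), (100, 100), "top")
        assert f.c_axis == (0.0, -1.0)
        assert f.r_axis == (1.0, 0.0)

    def test_explicit_angle_orthonormal(self):
        f = build_wound_frame(RECT, None, 30.0)
        assert f.c_axis[0] == pytest.approx(math.cos(math.radians(30)))
        assert f.c_axis[1] == pytest.approx(-math.sin(math.radians(30)))
        c, r = np.array(f.c_axis), np.array(f.r_axis)
        assert np.dot(c, r) == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(r) == pytest.approx(1.0)

    def test_degenerate_rectangle_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_wound_frame((10, 10, 0, 5), None, "right")

    def test_rectangle_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_wound_frame((90, 120, 0, 5), (50, 100), "right")


class TestDisplacementComponents:
    def frame(self):
        return build_wound_frame(RECT, None, "right")

    def test_parallel_step_effective_plus_one(self):
        d = displacement_components((0, 0, 0), (2, 0, 0), self.frame())
        assert d.oriented_distance == pytest.approx(2.0)
        assert d.lateral_distance == pytest.approx(0.0)
        assert d.effective_velocity == pytest.approx(1.0)

    def test_perpendicular_step_effective_zero(self):
        d = displacement_components((0, 0, 0), (0, 3, 0), self.frame())
        assert d.oriented_distance == pytest.approx(0.0)
        assert d.lateral_distance == pytest.approx(3.0)
        assert d.effective_velocity == pytest.approx(0.0)

    def test_retreating_diagonal(self):
        d = displacement_components((0, 0, 0), (-1, 1, 0), self.frame())
        assert d.effective_velocity == pytest.approx(-1 / math.sqrt(2))

    def test_away_step_effective_minus_one(self):
        d = displacement_components((5, 5, 0), (3, 5, 0), self.frame())
        assert d.effective_velocity == pytest.approx(-1.0)

    def test_zero_step_effective_zero(self):
        d = displacement_components((1, 1, 1), (1, 1, 1), self.frame())
        assert d.effective_velocity == 0.0
        assert d.absolute_distance == 0.0

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(-50, 50, allow_nan=False), min_size=6, max_size=6),
           st.floats(0, 360))
    def test_pythagorean_identity(self, coords, angle):
        """oriented^2 + lateral^2 + z^2 = absolute^2 for any displacement."""
        p0, p1 = coords[:3], coords[3:]
        frame = build_wound_frame(RECT, None, angle)
        d = displacement_components(p0, p1, frame)
        assert (d.oriented_distance ** 2 + d.lateral_distance ** 2 + d.z_distance ** 2
                == pytest.approx(d.absolute_distance ** 2, abs=1e-9))

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 360), st.floats(-30, 30), st.floats(-30, 30))
    def test_effective_velocity_rotation_invariant(self, rot, dx, dy):
        """Rotating both the frame and the step leaves the score unchanged."""
        base = build_wound_frame(RECT, None, 0.0)
        d0 = displacement_components((0, 0, 0), (dx, dy, 0), base)
        a = math.radians(rot)
        # rotate the step by -rot in image coords (y down), frame by angle rot
        rx = dx * math.cos(a) + dy * math.sin(a) * -1 * -1 - 0  # x' = x cos a - y(-sin a)
        rx = dx * math.cos(a) + dy * math.sin(a)
        ry = -dx * math.sin(a) + dy * math.cos(a)
        rotated = build_wound_frame(RECT, None, rot)
        d1 = displacement_components((0, 0, 0), (rx, ry, 0), rotated)
        assert d1.effective_velocity == pytest.approx(d0.effective_velocity, abs=1e-9)


class TestTrackMetrics:
    def frame(self):
        return build_wound_frame(RECT, None, "right")

    def test_straight_track_meandering_one(self):
        ts = make_trackset({1: [(t, 2.0 * t, 0, 0) for t in range(11)]})
        m = track_metrics(ts.track_dataframe(1), self.frame())
        assert m.meandering_index == pytest.approx(1.0)
        assert m.velocity == pytest.approx(2.0)
        assert m.oriented_velocity == pytest.approx(2.0)

    def test_out_and_back_meandering_zero(self):
        pts = [(t, 2.0 * t, 0, 0) for t in range(5)] + \
              [(5 + t, 8.0 - 2 * t, 0, 0) for t in range(5)]
        ts = make_trackset({1: pts})
        m = track_metrics(ts.track_dataframe(1), self.frame())
        assert m.meandering_index == pytest.approx(0.0)

    def test_l_shaped_track_five_sevenths(self):
        pts = ([(t, float(t), 0, 0) for t in range(4)] +          # 3 to the right
               [(4 + t, 3.0, float(t + 1), 0) for t in range(4)])  # 4 down
        ts = make_trackset({1: pts})
        m = track_metrics(ts.track_dataframe(1), self.frame())
        assert m.meandering_index == pytest.approx(5.0 / 7.0)

    def test_stationary_track_meandering_missing(self):
        ts = make_trackset({1: [(t, 5, 5, 0) for t in range(4)]})
        m = track_metrics(ts.track_dataframe(1), self.frame())
        assert m.meandering_index is None

    def test_physical_units(self):
        ts = make_trackset({1: [(t, 2.0 * t, 0, 0) for t in range(5)]})
        m = track_metrics(ts.track_dataframe(1), self.frame(), dt=0.5, pixel_size=0.34)
        assert m.velocity == pytest.approx(2.0 * 0.34 / 0.5)


class TestPopulationMetrics:
    def frame(self):
        return build_wound_frame(RECT, None, "right")

    def test_all_forward_population(self):
        ts = make_trackset({
            1: [(t, 10.0 + 3 * t, 20, 0) for t in range(10)],
            2: [(t, 5.0 + 3 * t, 60, 0) for t in range(10)],
        })
        m = population_metrics(ts, self.frame())
        assert m["forward_ratio"] == pytest.approx(1.0)
        assert m["backward_ratio"] == pytest.approx(0.0)

    def test_stationary_inside_wound(self):
        ts = make_trackset({
            1: [(t, 90.0, 50, 0) for t in range(6)],
            2: [(t, 85.0, 20, 0) for t in range(6)],
        })
        m = population_metrics(ts, self.frame())
        assert m["idle_wound_ratio"] == pytest.approx(1.0)
        assert m["in_wound_neutrophils"] == 2
        assert m["in_wound_ratio"] == pytest.approx(1.0)

    def test_enter_leave_fixture_counts(self):
        ts = make_trackset({
            1: [(t, 70.0 + 4 * t, 50, 0) for t in range(8)],   # enters and stays
            2: [(0, 75, 20, 0), (1, 82, 20, 0), (2, 90, 20, 0),
                (3, 82, 20, 0), (4, 70, 20, 0)],               # enters then leaves
            3: [(t, 10.0 + t, 80, 0) for t in range(8)],       # never enters
        })
        m = population_metrics(ts, self.frame())
        assert m["in_wound_neutrophils"] == 2
        assert m["transiting_wound_neutrophils"] == 1

    def test_forward_plus_backward_at_most_one(self):
        rng = np.random.default_rng(12)
        pts = {k: [(t, *rng.uniform(0, 100, 2), 0) for t in range(8)] for k in (1, 2, 3)}
        m = population_metrics(make_trackset(pts), self.frame())
        assert m["forward_ratio"] + m["backward_ratio"] <= 1.0

    def test_literal_backward_reading(self):
        ts = make_trackset({1: [(t, 10.0 + 3 * t, 20, 0) for t in range(5)]})
        m = population_metrics(ts, self.frame(), literal_backward=True)
        # every step has effective velocity +1 > -0.6, so the literal reading is 1
        assert m["backward_ratio"] == pytest.approx(1.0)

    def test_empty_denominators_reported_missing(self):
        ts = make_trackset({1: [(t, 10.0 + t, 80, 0) for t in range(4)]})
        m = population_metrics(ts, self.frame())
        assert m["in_wound_ratio_2"] is None
        assert m["idle_wound_ratio"] is None


class TestVolumeBandProfile:
    def migratory_trackset(self, n_cols=500, vol_fn=lambda x: 100.0, n_tracks=3):
        tracks = {}
        pts = []
        vols = []
        nid = 0
        rows = {}
        for k in range(n_tracks):
            ids = []
            for t in range(80):
                x = 6.25 * t + k * 1.7  # spans ~0..500 at 6.25 px/frame
                if x >= n_cols:
                    break
                nid += 1
                pts.append((t, x, 20.0 + 10 * k, 0.0))
                vols.append(vol_fn(x))
                ids.append(nid)
            tracks[k + 1] = ids
        from conftest import make_nodes
        from phagotrack.tracking import TrackSet
        return TrackSet(make_nodes(pts, volumes=vols), tracks)

    def test_band_partition_500_columns(self):
        ts = self.migratory_trackset()
        prof = volume_position_profile(ts, n_bands=25, band_width=20)
        assert len(prof.band_index) == 25
        assert prof.band_index[-1] == 25

    def test_constant_volume_flat_profile(self):
        ts = self.migratory_trackset()
        prof = volume_position_profile(ts, n_bands=25, band_width=20)
        assert prof.slope == pytest.approx(0.0, abs=1e-9)
        filled = prof.mean_volume[~np.isnan(prof.mean_volume)]
        assert np.allclose(filled, 1.0)

    def test_normalised_grand_mean_is_one(self):
        rng = np.random.default_rng(13)
        ts = self.migratory_trackset(vol_fn=lambda x: 50 + rng.uniform(0, 100))
        prof = volume_position_profile(ts, n_bands=25, band_width=20)
        # weighted by counts, the per-node normalised volumes average to 1
        filled = ~np.isnan(prof.mean_volume)
        grand = np.average(prof.mean_volume[filled], weights=prof.counts[filled])
        assert grand == pytest.approx(1.0, abs=1e-9)

    def test_linear_growth_recovered(self):
        g = 0.002  # relative volume increase per column
        ts = self.migratory_trackset(vol_fn=lambda x: 100.0 * (1 + g * x))
        prof = volume_position_profile(ts, n_bands=25, band_width=20)
        cols = ts.nodes["x"].to_numpy()
        expected = 20 * g * 100.0 / (100.0 * (1 + g * cols).mean())
        assert prof.p_value < 0.05
        assert prof.slope == pytest.approx(expected, rel=0.05)

    def test_no_surviving_tracks_names_filters(self):
        ts = make_trackset({1: [(t, t * 0.1, 0, 0) for t in range(5)]})
        with pytest.raises(ValueError, match="duration"):
            volume_position_profile(ts)
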