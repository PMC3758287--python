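"""Wound-oriented kinematics of cell tracks.

Chemotaxis toward a wound is quantified in a rotated coordinate frame: a
user-drawn rectangular "wound region" defines an axis ``c`` pointing toward
the wound and a lateral axis ``r`` perpendicular to it.  Each displacement
decomposes into an oriented component (along c), a lateral component (along
r) and, in 3D, a z component; the absolute displacement is their vector sum.
The effective velocity is the cosine of the angle between the in-plane
displacement and c: +1 heading straight at the wound, 0 perpendicular, -1
straight away.

Per-track summaries (mean velocities, meandering index) and the panel of
population measurements (wound arrivals, forward/backward ratios, idle and
transit statistics) are computed from those components, along with the
volume-vs-position band profile used to relate cell volume to proximity to
the wound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import TrackSet


@dataclass
class WoundFrame:
    """Wound rectangle plus the rotated (c, r) axis pair.

    ``rectangle`` is ``(x_min, x_max, y_min, y_max)`` in image pixels.
    ``c_axis`` is the in-plane unit vector toward the wound, ``r_axis`` the
    lateral unit vector (c rotated +90 deg).  Image y grows downward.
    """

    rectangle: tuple[float, float, float, float]
    c_axis: tuple[float, float]
    r_axis: tuple[float, float]

    def __post_init__(self) -> None:
        c = np.asarray(self.c_axis, dtype=float)
        r = np.asarray(self.r_axis, dtype=float)
        if not (math.isclose(np.linalg.norm(c), 1.0, abs_tol=1e-9)
                and math.isclose(np.linalg.norm(r), 1.0, abs_tol=1e-9)):
            raise ValueError("c_axis and r_axis must be unit vectors")
        if abs(float(np.dot(c, r))) > 1e-9:
            raise ValueError("c_axis and r_axis must be orthogonal")
        x0, x1, y0, y1 = self.rectangle
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate wound rectangle")

    def contains(self, x: float, y: float) -> bool:
        x0, x1, y0, y1 = self.rectangle
        return x0 <= x <= x1 and y0 <= y <= y1


@dataclass
class DisplacementRecord:
    """One inter-frame displacement decomposed in the wound frame.

    Distances are per-step (pixels or µm); ``effective_velocity`` is the
    dimensionless cosine score in [-1, 1]; ``in_wound`` is whether the step's
    end point lies inside the wound rectangle.
    """

    absolute_distance: float
    oriented_distance: float
    lateral_distance: float
    z_distance: float
    effective_velocity: float
    in_wound: bool
    dt: float


@dataclass
class TrackMetrics:
    """Per-track kinematic summary (velocities per unit time)."""

    track_id: int
    velocity: float
    oriented_velocity: float
    lateral_velocity: float
    meandering_index: float | None
    duration: int
    reached_wound: bool
    time_to_wound: int | None


def build_wound_frame(
    rectangle: Sequence[float],
    image_dims: tuple[int, int] | None = None,
    wound_side: str | float = "right",
) -> WoundFrame:
    """Construct the wound coordinate frame.

    ``wound_side`` is one of ``left/right/top/bottom`` (c points from the
    field toward that edge) or an explicit angle in degrees measured
    counter-clockwise from +x in conventional orientation (image y points
    down, so c = (cos a, -sin a)).  ``r`` is c rotated +90 deg in image
    coordinates.
    """
    x0, x1, y0, y1 = (float(v) for v in rectangle)
    if image_dims is not None:
        rows, cols = image_dims[0], image_dims[1]
        if not (0 <= x0 and x1 <= cols and 0 <= y0 and y1 <= rows):
            raise ValueError("wound rectangle lies outside the image")
    sides = {"right": (1.0, 0.0), "left": (-1.0, 0.0), "top": (0.0, -1.0), "bottom": (0.0, 1.0)}
    if isinstance(wound_side, str):
        if wound_side not in sides:
            raise ValueError(f"wound_side must be one of {sorted(sides)} or an angle")
        c = np.array(sides[wound_side])
    else:
        a = math.radians(float(wound_side))
        c = np.array([math.cos(a), -math.sin(a)])
    r = np.array([-c[1], c[0]])  # +90 deg rotation in (x, y-down) image coords
    return WoundFrame((x0, x1, y0, y1), tuple(c), tuple(r))


def displacement_components(p0, p1, frame: WoundFrame, dt: float = 1.0) -> DisplacementRecord:
    """Decompose the step ``p0 -> p1`` in the wound frame.

    Oriented and lateral distances are the projections of the in-plane step
    on c and r; the effective velocity is the cosine of the angle between the
    displacement and c (0 by convention for a zero step).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    step = p1 - p0
    xy = step[:2]
    dz = float(step[2]) if step.shape[0] > 2 else 0.0
    oriented = float(np.dot(xy, frame.c_axis))
    lateral = float(np.dot(xy, frame.r_axis))
    absolute = float(math.sqrt(oriented ** 2 + lateral ** 2 + dz ** 2))
    effective = oriented / absolute if absolute > 0 else 0.0
    in_wound = frame.contains(float(p1[0]), float(p1[1]))
    return DisplacementRecord(absolute, oriented, lateral, dz, effective, in_wound, dt)


def track_displacements(track_df: pd.DataFrame, frame: WoundFrame, dt: float = 1.0) -> list[DisplacementRecord]:
    pts = track_df[["x", "y", "z"]].to_numpy(dtype=float)
    return [displacement_components(pts[i], pts[i + 1], frame, dt) for i in range(len(pts) - 1)]


def track_metrics(
    track_df: pd.DataFrame,
    frame: WoundFrame,
    dt: float = 1.0,
    pixel_size: float = 1.0,
) -> TrackMetrics:
    """Kinematic summary of one track (>= 2 nodes, ordered by t).

    Velocities are mean per-step components divided by ``dt`` and scaled by
    ``pixel_size`` (µm/min when both metadata are present, px/frame
    otherwise).  The meandering index is the straight start-to-end distance
    over the travelled path length: 1 for a perfectly direct path, 0 for a
    closed loop; undefined (None) for a zero-length path.
    """
    if len(track_df) < 2:
        raise ValueError("track_metrics requires a track of length >= 2")
    disps = track_displacements(track_df, frame, dt)
    scale = pixel_size / dt
    vel = float(np.mean([d.absolute_distance for d in disps])) * scale
    ovel = float(np.mean([d.oriented_distance for d in disps])) * scale
    lvel = float(np.mean([d.lateral_distance for d in disps])) * scale
    pts = track_df[["x", "y", "z"]].to_numpy(dtype=float)
    path = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    mi = (chord / path) if path > 0 else None
    in_w = [frame.contains(x, y) for x, y in pts[:, :2]]
    reached = any(in_w)
    t_vals = track_df["t"].to_numpy()
    ttw = int(t_vals[in_w.index(True)] - t_vals[0]) if reached else None
    tid = int(track_df["track_id"].iloc[0]) if "track_id" in track_df and pd.notna(track_df["track_id"].iloc[0]) else -1
    return TrackMetrics(tid, vel, ovel, lvel, mi, len(track_df), reached, ttw)


def population_metrics(
    trackset: TrackSet,
    frame: WoundFrame,
    dt: float = 1.0,
    pixel_size: float = 1.0,
    forward_threshold: float = 0.6,
    idle_threshold: float = 0.5,
    literal_backward: bool = False,
) -> dict:
    """The full panel of population migration measurements.

    Per-track means (velocity, oriented velocity, lateral velocity,
    meandering index) are averaged over tracks; the population counts and
    ratios are:

    - ``in_wound_neutrophils``: tracks that reach the wound rectangle.
    - ``forward_ratio``: displacements with effective velocity > ``forward_threshold``
      over all displacements.
    - ``in_wound_ratio``: displacements inside the wound over all displacements.
    - ``in_wound_ratio_2``: displacements inside the wound over displacements
      made after the track first reached the wound.
    - ``idle_wound_ratio``: in-wound displacements slower than
      ``idle_threshold`` (absolute velocity, px/frame) over in-wound
      displacements.
    - ``backward_ratio``: displacements with effective velocity <
      ``-forward_threshold`` over all displacements (mirror of the forward
      criterion; ``literal_backward`` switches to > -threshold).
    - ``leave_wound_ratio``: same criterion restricted to displacements made
      after the wound was reached, over those displacements.
    - ``transiting_wound_neutrophils``: tracks that enter the wound and later
      leave it.

    Ratios whose denominator is empty are reported as None, not 0.
    """
    n_disp = 0
    n_forward = 0
    n_backward = 0
    n_in_wound = 0
    n_idle_in_wound = 0
    n_after_arrival = 0
    n_backward_after = 0
    n_in_wound_after = 0
    in_wound_tracks = 0
    transiting = 0
    per_track: list[TrackMetrics] = []

    for tid in sorted(trackset.tracks):
        df = trackset.track_dataframe(tid)
        if len(df) < 2:
            continue
        per_track.append(track_metrics(df, frame, dt, pixel_size))
        disps = track_displacements(df, frame, dt)
        pts = df[["x", "y", "z"]].to_numpy(dtype=float)
        inside = [frame.contains(x, y) for x, y in pts[:, :2]]
        arrived = inside.index(True) if any(inside) else None
        if arrived is not None:
            in_wound_tracks += 1
            if any(not i for i in inside[arrived:]):
                transiting += 1
        for k, d in enumerate(disps):
            n_disp += 1
            if d.effective_velocity > forward_threshold:
                n_forward += 1
            backward = (d.effective_velocity > -forward_threshold) if literal_backward \
                else (d.effective_velocity < -forward_threshold)
            if backward:
                n_backward += 1
            if d.in_wound:
                n_in_wound += 1
                if d.absolute_distance / d.dt < idle_threshold:
                    n_idle_in_wound += 1
            if arrived is not None and k + 1 > arrived:
                n_after_arrival += 1
                if backward:
                    n_backward_after += 1
                if d.in_wound:
                    n_in_wound_after += 1

    def ratio(num, den):
        return (num / den) if den else None

    return {
        "velocity": float(np.mean([m.velocity for m in per_track])) if per_track else None,
        "oriented_velocity": float(np.mean([m.oriented_velocity for m in per_track])) if per_track else None,
        "lateral_velocity": float(np.mean([m.lateral_velocity for m in per_track])) if per_track else None,
        "meandering_index": float(np.mean([m.meandering_index for m in per_track
                                           if m.meandering_index is not None]))
        if any(m.meandering_index is not None for m in per_track) else None,
        "in_wound_neutrophils": in_wound_tracks,
        "forward_ratio": ratio(n_forward, n_disp),
        "in_wound_ratio": ratio(n_in_wound, n_disp),
        "in_wound_ratio_2": ratio(n_in_wound_after, n_after_arrival),
        "idle_wound_ratio": ratio(n_idle_in_wound, n_in_wound),
        "backward_ratio": ratio(n_backward, n_disp),
        "leave_wound_ratio": ratio(n_backward_after, n_after_arrival),
        "transiting_wound_neutrophils": transiting,
        "n_tracks": len(per_track),
        "n_displacements": n_disp,
    }


@dataclass
class VolumeBandProfile:
    """Mean normalised cell volume in adjacent column bands across the field.

    Bands index 1..n_bands along the image column axis (higher index closer
    to the wound when the wound sits at the right edge).  Volumes are
    normalised so the grand mean over all contributing nodes is 1 per
    dataset; an OLS fit of normalised volume against band index tests for a
    spatial volume trend.
    """

    band_index: np.ndarray
    mean_volume: np.ndarray
    counts: np.ndarray
    normalisation: float
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def volume_position_profile(
    trackset: TrackSet,
    n_bands: int = 25,
    band_width: int = 20,
    min_duration: int = 30,
    min_velocity: float = 2.0,
    col_origin: float = 0.0,
) -> VolumeBandProfile:
    """Volume-vs-position analysis of migratory cells.

    Tracks are filtered to migratory cells: duration > ``min_duration``
    frames and mean absolute velocity >= ``min_velocity`` px/frame (defaults
    match long tracks spanning more than 30 time points moving at >= 2
    pixels/time point).  Every node of a surviving track is binned by
    centroid column into ``n_bands`` adjacent bands of ``band_width`` columns
    starting at ``col_origin``; volumes are averaged per band and normalised
    to the mean volume of the contributing nodes so the grand mean is 1.
    An ordinary-least-squares regression of normalised node volume on band
    index provides the slope, its two-sided t-test p-value and r^2.

    Raises
    ------
    ValueError
        If no track passes the filters (the message names them).
    """
    kept_nodes = []
    for tid in sorted(trackset.tracks):
        df = trackset.track_dataframe(tid)
        if len(df) < 2:
            continue
        duration = int(df["t"].max() - df["t"].min()) + 1
        pts = df[["x", "y", "z"]].to_numpy(dtype=float)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        mean_speed = float(steps.mean())
        if duration > min_duration and mean_speed >= min_velocity:
            kept_nodes.append(df)
    if not kept_nodes:
        raise ValueError(
            f"no tracks pass the migratory filters (duration > {min_duration} frames "
            f"and mean velocity >= {min_velocity} px/frame)"
        )
    allnodes = pd.concat(kept_nodes, ignore_index=True)
    band = np.floor((allnodes["x"].to_numpy(dtype=float) - col_origin) / band_width).astype(int) + 1
    in_range = (band >= 1) & (band <= n_bands)
    band = band[in_range]
    vols = allnodes["volume"].to_numpy(dtype=float)[in_range]
    if len(vols) == 0:
        raise ValueError("no nodes fall inside the banded field")
    norm = float(vols.mean())
    nvols = vols / norm
    idx = np.arange(1, n_bands + 1)
    mean_v = np.full(n_bands, np.nan)
    counts = np.zeros(n_bands, dtype=int)
    for b in idx:
        sel = band == b
        counts[b - 1] = int(sel.sum())
        if counts[b - 1]:
            mean_v[b - 1] = float(nvols[sel].mean())
    fit = stats.linregress(band.astype(float), nvols)
    return VolumeBandProfile(
        band_index=idx, mean_volume=mean_v, counts=counts, normalisation=norm,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2), p_value=float(fit.pvalue),
    )
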