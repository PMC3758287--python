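"""Shared fixtures: small synthetic recordings and hand-built node tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phagotrack import SyntheticSpec, generate_dataset
from phagotrack.synthesis import sinusoid_path, straight_path
from phagotrack.tracking import NODE_COLUMNS, TrackSet, _normalise_nodes
from phagotrack.volume_io import VolumeStack, VolumeSequence


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A fast, small-field benchmark used by most integration tests.

    Paths are explicit and well separated (the default path library is laid
    out for the full-size field, where fractional positions would cram the
    cells together in a 96-pixel field).
    """
    n_t = 25
    return SyntheticSpec(
        n_cells=3, n_timepoints=n_t, rows=96, cols=96, slices=9,
        paths=[
            straight_path((12, 16, 4), (84, 20, 4), n_t),
            sinusoid_path((12, 48, 4), (84, 46, 4), n_t, amplitude=6, cycles=2),
            straight_path((14, 78, 3), (84, 82, 3), n_t, activation=8),
        ],
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec, seed=11)


def make_nodes(points, volumes=None) -> pd.DataFrame:
    """Node table from [(t, x, y, z), ...]; volumes default to 100."""
    rows = []
    for i, (t, x, y, z) in enumerate(points, start=1):
        rows.append(dict(node_id=i, t=t, x=float(x), y=float(y), z=float(z),
                         volume=float(volumes[i - 1]) if volumes is not None else 100.0,
                         mean_intensity=1.0, frame_label=1, parent_id=pd.NA,
                         child_id=pd.NA, track_id=pd.NA, interpolated=False))
    return _normalise_nodes(pd.DataFrame(rows, columns=NODE_COLUMNS))


def make_trackset(track_points: dict[int, list[tuple]]) -> TrackSet:
    """TrackSet from {track_id: [(t, x, y, z), ...]} with unit volumes."""
    pts = []
    tracks = {}
    nid = 0
    for tid, plist in track_points.items():
        ids = []
        for p in plist:
            nid += 1
            pts.append(p)
            ids.append(nid)
        tracks[tid] = ids
    return TrackSet(make_nodes(pts), tracks)


def stack_of(arr, **kw) -> VolumeStack:
    return VolumeStack(np.asarray(arr, dtype=float), **kw)


def seq_of(arrays, **kw) -> VolumeSequence:
    stacks = [VolumeStack(np.asarray(a, dtype=float), time_index=i, **kw)
              for i, a in enumerate(arrays)]
    return VolumeSequence.from_stacks(stacks)
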