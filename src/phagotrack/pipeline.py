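"""End-to-end orchestration: read -> reduce -> segment -> track -> measure.

:class:`PipelineConfig` gathers every tunable of the individual stages and is
validated strictly (unknown keys are rejected before any computation).
:func:`run_pipeline` executes the full chain and returns a
:class:`ResultsBundle` with the processed sequence, labelled stacks, node
table, track set, kinematic measurements and a run manifest sufficient to
re-execute the run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import volume_io
from .volume_io import VolumeSequence, VolumeStack
from .segmentation import SegmentationParams, segment_sequence, split_volume_outliers
from .tracking import (
    KeyholeParams, TrackSet, nodes_from_segmentation, link_sequence,
    backward_validate, bridge_gaps, resolve_collisions,
)
from .kinematics import build_wound_frame, population_metrics, track_metrics

logger = logging.getLogger("phagotrack")


@dataclass
class PipelineConfig:
    """All pipeline tunables in one validated record.

    Unknown keys in a config file are rejected; every field name below is
    the schema.  ``wound`` is ``(x_min, x_max, y_min, y_max)`` in processed
    pixels and enables the kinematics stage.
    """

    # io / pre-processing
    layout: str = "auto"
    reduce: bool = True
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_interval: float = 1.0
    channel_overrides: dict = field(default_factory=dict)
    # segmentation
    threshold_fraction: float = 1.0
    low_threshold: float | None = None
    high_threshold: float | None = None
    connectivity: int = 26
    outlier_k: float = 3.0
    per_timepoint_otsu: bool = False
    erode_in_plane: bool = False
    # tracking
    wedge_angle: float = 60.0
    circle_angle: float = 300.0
    wedge_reach: float = 3.0
    circle_radius: float = 1.0
    first_link_radius: float | None = None
    gap_roi_radius: float | None = None
    min_keyhole_radius: float | None = None
    collision_volume_ratio: float = 1.5
    idle_tolerance: float = 0.5
    max_gap: int = 1
    use_2d: bool = False
    backward_first_link_only: bool = False
    resolve_collisions: bool = True
    # kinematics
    wound: tuple[float, float, float, float] | None = None
    wound_side: str = "right"
    forward_threshold: float = 0.6
    idle_threshold: float = 0.5
    literal_backward: bool = False
    n_bands: int = 25
    band_width: int = 20
    min_track_duration: int = 30
    min_track_velocity: float = 2.0
    # misc
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("voxel_size", "wound"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def with_updates(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            low_threshold=self.low_threshold, high_threshold=self.high_threshold,
            threshold_fraction=self.threshold_fraction, connectivity=self.connectivity,
            outlier_k=self.outlier_k, per_timepoint_otsu=self.per_timepoint_otsu,
            erode_in_plane=self.erode_in_plane,
        )

    def keyhole_params(self) -> KeyholeParams:
        return KeyholeParams(
            wedge_angle=self.wedge_angle, circle_angle=self.circle_angle,
            wedge_reach=self.wedge_reach, circle_radius=self.circle_radius,
            first_link_radius=self.first_link_radius, gap_roi_radius=self.gap_roi_radius,
            min_radius=self.min_keyhole_radius,
            collision_volume_ratio=self.collision_volume_ratio,
            idle_tolerance=self.idle_tolerance, max_gap=self.max_gap, use_2d=self.use_2d,
            backward_first_link_only=self.backward_first_link_only,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["voxel_size"] = list(d["voxel_size"])
        if d["wound"] is not None:
            d["wound"] = list(d["wound"])
        return d


@dataclass
class ResultsBundle:
    """Everything a pipeline run produces."""

    seq: VolumeSequence
    labeled_seq: list
    trackset: TrackSet
    population: dict | None
    per_track: pd.DataFrame | None
    manifest: dict
    scale_to_original: tuple[float, float, float]


def run_pipeline(source, config: PipelineConfig | None = None) -> ResultsBundle:
    """Run the full chain on a path or an in-memory sequence.

    Stages: read -> channel classification -> 2x2 reduction (optional) ->
    hysteresis segmentation -> volume-outlier splitting -> keyhole linking ->
    backward validation -> gap bridging -> collision resolution ->
    kinematics (when a wound rectangle is configured).  The manifest records
    the config, package version, seed and per-stage object/track counts; any
    stage failure is recorded in the manifest before the exception
    propagates.
    """
    from . import __version__

    config = config or PipelineConfig()
    manifest: dict = {"config": config.to_dict(), "version": __version__, "stages": {}}

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][name] = f"FAILED: {type(exc).__name__}: {exc}"
            manifest["failed_at"] = name
            raise
        return result

    if isinstance(source, VolumeSequence):
        seq = source
    else:
        seq = stage("read", lambda: volume_io.read_sequence(
            source, config.layout, voxel_size=config.voxel_size,
            frame_interval=config.frame_interval))
    manifest["stages"]["read"] = {"n_timepoints": seq.n_timepoints, "shape": list(seq.frame_shape)}

    stage("classify_channels", lambda: volume_io.classify_channels(
        seq, overrides={int(k): v for k, v in config.channel_overrides.items()} or None))
    manifest["stages"]["classify_channels"] = {"labels": list(seq.channel_labels)}

    scale = (1.0, 1.0, 1.0)
    if config.reduce:
        seq = stage("reduce", lambda: volume_io.reduce_sequence(seq))
        scale = (2.0, 2.0, 1.0)
        manifest["stages"]["reduce"] = {"shape": list(seq.frame_shape)}

    seg_params = config.segmentation_params()
    labeled_seq = stage("segment", lambda: segment_sequence(seq, seg_params))
    manifest["stages"]["segment"] = {"n_objects": int(sum(len(r) for _, r in labeled_seq))}

    labeled_seq = stage("split_outliers", lambda: split_volume_outliers(
        labeled_seq, seg_params, intensity_stacks=seq.stacks))
    manifest["stages"]["split_outliers"] = {
        "n_objects": int(sum(len(r) for _, r in labeled_seq))}

    nodes = nodes_from_segmentation(labeled_seq)
    key_params = config.keyhole_params().resolved(nodes)
    trackset = stage("link", lambda: link_sequence(nodes, key_params))
    manifest["stages"]["link"] = {"n_tracks": trackset.n_tracks}
    trackset = stage("backward_validate", lambda: backward_validate(trackset, key_params))
    manifest["stages"]["backward_validate"] = {"n_tracks": trackset.n_tracks}
    trackset = stage("bridge_gaps", lambda: bridge_gaps(trackset, key_params))
    manifest["stages"]["bridge_gaps"] = {"n_tracks": trackset.n_tracks}
    if config.resolve_collisions:
        def _resolve():
            return resolve_collisions(trackset, labeled_seq, key_params,
                                      intensity_stacks=seq.stacks,
                                      connectivity=config.connectivity)
        trackset, labeled_seq = stage("resolve_collisions", _resolve)
        manifest["stages"]["resolve_collisions"] = {
            "n_tracks": trackset.n_tracks,
            "n_events": len(trackset.events),
        }

    population = None
    per_track = None
    if config.wound is not None:
        def _measure():
            frame = build_wound_frame(config.wound, seq.frame_shape[:2], config.wound_side)
            ref = seq.stacks[0]
            pop = population_metrics(
                trackset, frame, dt=ref.frame_interval, pixel_size=ref.voxel_size[0],
                forward_threshold=config.forward_threshold,
                idle_threshold=config.idle_threshold,
                literal_backward=config.literal_backward,
            )
            rows = []
            for tid in sorted(trackset.tracks):
                df = trackset.track_dataframe(tid)
                if len(df) < 2:
                    continue
                m = track_metrics(df, frame, dt=ref.frame_interval, pixel_size=ref.voxel_size[0])
                rows.append(vars(m))
            return pop, pd.DataFrame(rows)
        population, per_track = stage("measure", _measure)
        manifest["stages"]["measure"] = {"n_tracks_measured": 0 if per_track is None else len(per_track)}

    manifest["seed"] = config.seed
    bundle = ResultsBundle(seq, labeled_seq, trackset, population, per_track, manifest, scale)
    if config.output_dir is not None:
        export_tables(bundle, Path(config.output_dir))
    return bundle


def export_tables(bundle: ResultsBundle, out_dir: str | Path, formats=("csv", "json")) -> list[Path]:
    """Write the node table, track set, metrics and manifest to disk.

    Column order is stable; the manifest embeds a checksum of the node table
    so a run can be verified byte-for-byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    nodes_path = out_dir / "nodes.csv"
    bundle.trackset.nodes.to_csv(nodes_path, index=False)
    written.append(nodes_path)

    tracks_path = out_dir / "tracks.json"
    tracks_path.write_text(bundle.trackset.to_json())
    written.append(tracks_path)

    if bundle.trackset.events:
        events_path = out_dir / "events.jsonl"
        events_path.write_text("\n".join(json.dumps(e) for e in bundle.trackset.events) + "\n")
        written.append(events_path)

    if bundle.population is not None:
        pop_path = out_dir / "population_metrics.json"
        pop_path.write_text(json.dumps(bundle.population, indent=1))
        written.append(pop_path)
    if bundle.per_track is not None and len(bundle.per_track):
        pt_path = out_dir / "track_metrics.csv"
        bundle.per_track.to_csv(pt_path, index=False)
        written.append(pt_path)

    manifest = dict(bundle.manifest)
    manifest["node_table_sha256"] = hashlib.sha256(nodes_path.read_bytes()).hexdigest()
    man_path = out_dir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=1))
    written.append(man_path)
    return written


def import_nodes(path: str | Path) -> pd.DataFrame:
    """Read a node table CSV back, restoring nullable-integer columns."""
    df = pd.read_csv(path)
    for col in ("parent_id", "child_id", "track_id"):
        df[col] = df[col].astype("Int64")
    return df
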