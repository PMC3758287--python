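"""Reading, writing and pre-processing of time-lapse volume sequences.

A recording is a series of 3D intensity grids, one per time point, in one of
three on-disk layouts:

``slice_folders``
    One directory per time point, each holding one single-page TIFF per
    z-slice (sorted lexicographically).
``multipage_tiff``
    One directory per time point holding a single multi-page TIFF whose pages
    are the z-slices, or a flat directory of one multi-page TIFF per time
    point.
``serialized``
    One ``.npy`` file per time point containing a 3D grid, with an optional
    ``metadata.json`` sidecar (versioned; see :data:`SERIALIZED_VERSION`).

Axis convention: arrays are indexed ``(row y, column x, slice z)`` and all
coordinates in the package are 0-based ``(x, y, z)`` in pixels of the grid
they were measured on.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

SERIALIZED_VERSION = 1

LAYOUTS = ("slice_folders", "multipage_tiff", "serialized", "auto")

#: Suffixes mirroring the conventional output-folder naming: original,
#: reduced, labelled and final-results folders derived from a dataset name.
FOLDER_SUFFIXES = {"original": "_Or", "reduced": "_Re", "labeled": "_La", "results": "_Ha"}


@dataclass
class VolumeStack:
    """One time point's 3D fluorescence (or DIC) intensity grid.

    Parameters
    ----------
    intensities
        Non-negative array of shape ``(rows, cols, slices)`` = (y, x, z).
    time_index
        Acquisition index of this stack, >= 0.
    voxel_size
        ``(dy, dx, dz)`` in micrometres.  Defaults to 1 so that measurements
        fall back to pixel units.
    frame_interval
        Minutes between consecutive time points.
    bit_depth
        Nominal bit depth of the source data (used at export quantisation).
    """

    intensities: np.ndarray
    time_index: int = 0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_interval: float = 1.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim == 2:
            self.intensities = self.intensities[:, :, np.newaxis]
        if self.intensities.ndim != 3:
            raise ValueError(f"intensities must be 3D, got shape {self.intensities.shape}")
        if any(s <= 0 for s in self.intensities.shape):
            raise ValueError(f"all dimensions must be > 0, got {self.intensities.shape}")
        if self.intensities.size and float(self.intensities.min()) < 0:
            raise ValueError("intensities must be non-negative")
        if self.time_index < 0:
            raise ValueError("time_index must be >= 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class VolumeSequence:
    """An ordered multi-channel time series of :class:`VolumeStack`.

    ``channel_stacks[c][i]`` is channel ``c`` at the ``i``-th time point.
    ``stacks`` exposes the primary (first fluorescent, else first) channel,
    which is what the segmentation and tracking stages consume.
    """

    channel_stacks: list[list[VolumeStack]]
    channel_labels: list[str] = field(default_factory=list)
    source_layout: str = "serialized"

    def __post_init__(self) -> None:
        if not self.channel_stacks or not self.channel_stacks[0]:
            raise ValueError("VolumeSequence requires at least one channel with one stack")
        if not self.channel_labels:
            self.channel_labels = ["fluorescent"] * len(self.channel_stacks)
        if len(self.channel_labels) != len(self.channel_stacks):
            raise ValueError("channel_labels must match number of channels")
        ref = self.channel_stacks[0][0]
        for ch in self.channel_stacks:
            times = [s.time_index for s in ch]
            if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
                raise ValueError(f"time_index must be strictly increasing, got {times}")
            for s in ch:
                if s.shape != ref.shape:
                    raise ValueError(
                        f"stack at t={s.time_index} has shape {s.shape}, expected {ref.shape}"
                    )
                if s.voxel_size != ref.voxel_size:
                    raise ValueError("all stacks must share voxel_size")

    @classmethod
    def from_stacks(cls, stacks: Sequence[VolumeStack], **kw) -> "VolumeSequence":
        return cls(channel_stacks=[list(stacks)], **kw)

    @property
    def stacks(self) -> list[VolumeStack]:
        for label, ch in zip(self.channel_labels, self.channel_stacks):
            if label == "fluorescent":
                return ch
        return self.channel_stacks[0]

    @property
    def n_timepoints(self) -> int:
        return len(self.channel_stacks[0])

    @property
    def frame_shape(self) -> tuple[int, int, int]:
        return self.channel_stacks[0][0].shape


@dataclass
class ChannelProfile:
    """Histogram summary used to tell fluorescent from DIC channels.

    Fluorescent channels pile most voxels near zero (sparse bright cells on a
    dark background); DIC channels centre their histogram mid-range.
    ``low_fraction`` is the fraction of voxels in the lowest quarter of the
    channel's observed dynamic range, which makes the statistic invariant to
    global intensity rescaling.
    """

    histogram: np.ndarray
    low_fraction: float
    inferred_type: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_fraction <= 1.0:
            raise ValueError("low_fraction must lie in [0, 1]")


_INT_RE = re.compile(r"(\d+)")


def _numeric_key(name: str) -> tuple:
    """Sort key that orders embedded integers numerically (T2 before T10)."""
    parts = _INT_RE.split(name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _trailing_int(name: str) -> int | None:
    m = re.search(r"(\d+)(?=\D*$)", name)
    return int(m.group(1)) if m else None


def _check_contiguous(names: list[str]) -> None:
    """Raise if integer-suffixed time point names skip an index."""
    indices = [_trailing_int(n) for n in names]
    if any(i is None for i in indices):
        return  # unnumbered names: accept lexicographic order
    for prev, cur in zip(indices, indices[1:]):
        if cur != prev + 1:
            raise ValueError(
                f"time points are not contiguous: missing time point {prev + 1} "
                f"(found {prev} then {cur})"
            )


def _read_tiff_zyx(path: Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis, :, :]
    return arr


def _zyx_to_yxz(arr: np.ndarray) -> np.ndarray:
    return np.moveaxis(arr, 0, 2)


def _detect_layout(path: Path, meta: dict) -> str:
    """Infer the on-disk layout from the metadata sidecar or the file mix."""
    if meta.get("layout") in LAYOUTS[:3]:
        return meta["layout"]
    if any(path.glob("*.npy")):
        return "serialized"
    if any(path.glob("*.tif*")):
        return "multipage_tiff"
    for sub in path.iterdir():
        if sub.is_dir():
            n_tifs = len(list(sub.glob("*.tif*")))
            if n_tifs > 1:
                return "slice_folders"
            if n_tifs == 1:
                return "multipage_tiff"
    raise FileNotFoundError(f"could not detect a volume layout under {path}")


def read_sequence(path: str | Path, layout: str = "auto", *, voxel_size=(1.0, 1.0, 1.0),
                  frame_interval: float = 1.0) -> VolumeSequence:
    """Read a time-lapse recording from disk.

    Parameters
    ----------
    path
        Directory containing the per-time-point folders or files.
    layout
        One of :data:`LAYOUTS`.
    voxel_size, frame_interval
        Metadata applied to every stack; overridden by a ``metadata.json``
        sidecar in ``path`` if one is present (keys ``voxel_size``,
        ``frame_interval``).

    Raises
    ------
    ValueError
        If the layout is unknown, a time point is missing from a numbered
        series (the first gap is named), or stacks disagree in shape.
    FileNotFoundError
        If ``path`` does not exist or holds no readable time points.
    """
    path = Path(path)
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")

    meta_path = path / "metadata.json"
    meta = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        voxel_size = tuple(meta.get("voxel_size", voxel_size))
        frame_interval = float(meta.get("frame_interval", frame_interval))
    if layout == "auto":
        layout = _detect_layout(path, meta)

    grids: list[np.ndarray] = []
    if layout == "slice_folders":
        folders = sorted((p for p in path.iterdir() if p.is_dir()), key=lambda p: _numeric_key(p.name))
        if not folders:
            raise FileNotFoundError(f"no time-point folders under {path}")
        _check_contiguous([f.name for f in folders])
        for folder in folders:
            slices = sorted(folder.glob("*.tif*"), key=lambda p: _numeric_key(p.name))
            if not slices:
                raise FileNotFoundError(f"no TIFF slices in {folder}")
            planes = [tifffile.imread(str(s)) for s in slices]
            shapes = {p.shape for p in planes}
            if len(shapes) != 1:
                raise ValueError(f"mixed slice dimensions in {folder}: {sorted(shapes)}")
            grids.append(_zyx_to_yxz(np.stack(planes, axis=0)))
    elif layout == "multipage_tiff":
        folders = sorted((p for p in path.iterdir() if p.is_dir()), key=lambda p: _numeric_key(p.name))
        if folders:
            _check_contiguous([f.name for f in folders])
            files = []
            for folder in folders:
                tifs = sorted(folder.glob("*.tif*"))
                if len(tifs) != 1:
                    raise ValueError(f"expected exactly one multipage TIFF in {folder}, found {len(tifs)}")
                files.append(tifs[0])
        else:
            files = sorted(path.glob("*.tif*"), key=lambda p: _numeric_key(p.name))
            if not files:
                raise FileNotFoundError(f"no TIFF time points under {path}")
            _check_contiguous([f.stem for f in files])
        grids = [_zyx_to_yxz(_read_tiff_zyx(f)) for f in files]
    else:  # serialized
        files = sorted(path.glob("*.npy"), key=lambda p: _numeric_key(p.name))
        if not files:
            raise FileNotFoundError(f"no serialized time points (.npy) under {path}")
        _check_contiguous([f.stem for f in files])
        grids = [np.load(f) for f in files]
        grids = [g if g.ndim == 3 else g[:, :, np.newaxis] for g in grids]

    ref_shape = grids[0].shape
    for i, g in enumerate(grids):
        if g.shape != ref_shape:
            raise ValueError(
                f"mixed stack dimensions: time point {i} has shape {g.shape}, expected {ref_shape}"
            )
    stacks = [
        VolumeStack(g, time_index=i, voxel_size=tuple(voxel_size), frame_interval=frame_interval)
        for i, g in enumerate(grids)
    ]
    return VolumeSequence.from_stacks(stacks, source_layout=layout)


def write_sequence(seq: VolumeSequence, path: str | Path, layout: str = "serialized") -> Path:
    """Write the primary channel of ``seq`` to disk in the given layout."""
    path = Path(path)
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")
    path.mkdir(parents=True, exist_ok=True)
    n = seq.n_timepoints
    width = max(4, len(str(n)))
    for i, stack in enumerate(seq.stacks):
        tag = f"T{i:0{width}d}"
        if layout == "serialized":
            np.save(path / f"{tag}.npy", stack.intensities)
        elif layout == "multipage_tiff":
            tifffile.imwrite(str(path / f"{tag}.tif"), np.moveaxis(stack.intensities, 2, 0),
                             photometric="minisblack")
        else:
            folder = path / tag
            folder.mkdir(exist_ok=True)
            for z in range(stack.shape[2]):
                tifffile.imwrite(str(folder / f"Z{z:04d}.tif"), stack.intensities[:, :, z],
                                 photometric="minisblack")
    ref = seq.stacks[0]
    meta = {
        "version": SERIALIZED_VERSION,
        "layout": layout,
        "n_timepoints": n,
        "voxel_size": list(ref.voxel_size),
        "frame_interval": ref.frame_interval,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    return path


def channel_profile(stacks: Iterable[VolumeStack], *, n_bins: int = 256,
                    low_range_fraction: float = 0.25, cutoff: float = 0.85) -> ChannelProfile:
    """Profile one channel's pooled intensity histogram and classify it."""
    data = [s.intensities for s in stacks]
    if not data or all(d.size == 0 for d in data):
        raise ValueError("cannot profile an empty channel")
    lo = min(float(d.min()) for d in data)
    hi = max(float(d.max()) for d in data)
    if hi <= lo:
        # Constant channel: all voxels are trivially 'low'; call it fluorescent.
        hist = np.zeros(n_bins, dtype=np.int64)
        hist[0] = sum(d.size for d in data)
        return ChannelProfile(hist, 1.0, "fluorescent")
    hist = np.zeros(n_bins, dtype=np.int64)
    for d in data:
        h, _ = np.histogram(d, bins=n_bins, range=(lo, hi))
        hist += h
    total = int(hist.sum())
    low_cut = lo + low_range_fraction * (hi - lo)
    low = sum(int(np.count_nonzero(d < low_cut)) for d in data)
    low_fraction = low / total
    inferred = "fluorescent" if low_fraction >= cutoff else "dic"
    return ChannelProfile(hist, low_fraction, inferred)


def classify_channels(seq: VolumeSequence, *, cutoff: float = 0.85,
                      overrides: dict[int, str] | None = None) -> list[ChannelProfile]:
    """Classify every channel of ``seq`` as fluorescent or DIC.

    A channel is called fluorescent when at least ``cutoff`` of its voxels lie
    in the lowest quarter of its observed dynamic range.  ``overrides`` maps
    channel index to a forced label.  ``seq.channel_labels`` is updated in
    place with the inferred (or overridden) tags.
    """
    profiles = []
    for c, ch in enumerate(seq.channel_stacks):
        prof = channel_profile(ch, cutoff=cutoff)
        if overrides and c in overrides:
            if overrides[c] not in ("fluorescent", "dic"):
                raise ValueError(f"invalid channel override {overrides[c]!r}")
            prof.inferred_type = overrides[c]
        seq.channel_labels[c] = prof.inferred_type
        profiles.append(prof)
    return profiles


def reduce_stack(stack: VolumeStack) -> VolumeStack:
    """Halve in-plane resolution by averaging 2x2 voxel blocks on each slice.

    Smoothing-and-subsampling noise reduction: each output voxel is the mean
    of a 2x2 in-plane block; the slice count is unchanged and the in-plane
    voxel size doubles.  Odd trailing rows/columns are cropped so that blocks
    stay contiguous.
    """
    rows, cols, _ = stack.shape
    if rows < 2 or cols < 2:
        raise ValueError(f"need at least 2 rows and columns to reduce, got {stack.shape}")
    r2, c2 = rows // 2, cols // 2
    v = stack.intensities[: 2 * r2, : 2 * c2, :].astype(np.float64)
    reduced = v.reshape(r2, 2, c2, 2, -1).mean(axis=(1, 3))
    dy, dx, dz = stack.voxel_size
    return replace(stack, intensities=reduced, voxel_size=(2 * dy, 2 * dx, dz))


def reduce_sequence(seq: VolumeSequence) -> VolumeSequence:
    """Apply :func:`reduce_stack` to every stack of every channel."""
    return VolumeSequence(
        channel_stacks=[[reduce_stack(s) for s in ch] for ch in seq.channel_stacks],
        channel_labels=list(seq.channel_labels),
        source_layout=seq.source_layout,
    )
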