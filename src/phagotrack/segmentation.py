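"""Double-hysteresis-threshold segmentation of 3D fluorescence stacks.

Cells are bright blobs whose intensity falls off toward the background, so a
single threshold either leaks background in (too low) or shatters one cell
into fragments (too high).  The Schmitt-trigger-style double threshold keeps
a connected region of the low threshold only if it contains at least one
voxel above the high threshold.  Both thresholds come from a 3-class Otsu
partition of the intensity histogram (background / dim cell rim / bright cell
core), optionally rescaled by a user fraction.

Objects whose volume is an outlier of the pooled volume distribution
(mean + k.std over every object at every time point) are assumed to be two
touching cells and are split by sequential erosion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .volume_io import VolumeStack, VolumeSequence


@dataclass
class SegmentationParams:
    """Tunables of the segmentation stage.

    ``threshold_fraction`` rescales both automatic thresholds (1.0 = use the
    Otsu values as-is; the robustness sweep varies it 0.4-1.4).
    ``connectivity`` is the 3D voxel adjacency (6 face or 26 full).
    ``outlier_k`` sets the volume-outlier cut at mean + k.std.
    ``per_timepoint_otsu`` computes thresholds per stack instead of on the
    pooled histogram of the whole sequence.
    ``erode_in_plane`` restricts outlier-splitting erosion to x-y, for
    acquisitions whose z step is much larger than the pixel size.
    """

    low_threshold: float | None = None
    high_threshold: float | None = None
    threshold_fraction: float = 1.0
    connectivity: int = 26
    outlier_k: float = 3.0
    n_bins: int = 256
    histogram_weighting: str = "log"
    per_timepoint_otsu: bool = False
    erode_in_plane: bool = False

    def __post_init__(self) -> None:
        if self.threshold_fraction <= 0:
            raise ValueError("threshold_fraction must be > 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.histogram_weighting not in ("log", "counts"):
            raise ValueError("histogram_weighting must be 'log' or 'counts'")
        if (
            self.low_threshold is not None
            and self.high_threshold is not None
            and not 0 <= self.low_threshold <= self.high_threshold
        ):
            raise ValueError("need 0 <= low_threshold <= high_threshold")


@dataclass
class LabeledStack:
    """Integer object labels for one time point (0 = background)."""

    labels: np.ndarray
    time_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass
class RegionRecord:
    """Geometry and intensity summary of one labelled object.

    ``centroid`` is ``(x, y, z)`` in 0-based pixels of the segmented grid;
    ``bbox`` is ``(y0, y1, x0, x1, z0, z1)`` half-open.  ``split_from`` marks
    objects produced by outlier splitting; ``unsplittable`` flags outliers
    that eroded away before separating and were left intact.
    """

    label: int
    centroid: tuple[float, float, float]
    volume: int
    mean_intensity: float
    bbox: tuple[int, int, int, int, int, int]
    time_index: int = 0
    split_from: int | None = None
    unsplittable: bool = False


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def _pooled_histogram(stacks: Sequence[VolumeStack], n_bins: int):
    lo = min(float(s.intensities.min()) for s in stacks)
    hi = max(float(s.intensities.max()) for s in stacks)
    if hi <= lo:
        raise ValueError("cannot compute thresholds of a constant sequence")
    counts = np.zeros(n_bins, dtype=np.int64)
    for s in stacks:
        h, edges = np.histogram(s.intensities, bins=n_bins, range=(lo, hi))
        counts += h
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def auto_thresholds(
    source: VolumeStack | VolumeSequence | Sequence[VolumeStack],
    params: SegmentationParams | None = None,
) -> tuple[float, float]:
    """Automatic (low, high) hysteresis thresholds.

    The two boundaries of a 3-class Otsu partition (maximising between-class
    variance over all threshold pairs of a ``n_bins``-bin histogram) are
    rescaled by ``params.threshold_fraction``.  When given a sequence the
    histogram is pooled over all time points so thresholds are consistent
    along the recording.

    Sparse-foreground fluorescence volumes put the overwhelming majority of
    voxels in the background class, and a count-weighted Otsu partition then
    prefers to subdivide the background noise bulge rather than isolate the
    minority cell class.  The default ``histogram_weighting='log'`` applies
    the partition to log(1 + count) histogram weights, which rebalances the
    classes while leaving well-balanced histograms essentially unchanged;
    set ``'counts'`` for the classic partition.

    Raises
    ------
    ValueError
        If the data are constant (no threshold separates anything).
    """
    params = params or SegmentationParams()
    if isinstance(source, VolumeStack):
        stacks = [source]
    elif isinstance(source, VolumeSequence):
        stacks = source.stacks
    else:
        stacks = list(source)
    counts, centers = _pooled_histogram(stacks, params.n_bins)
    if np.count_nonzero(counts) < 3:
        # Fewer than 3 occupied bins: place boundaries between occupied levels.
        occ = centers[counts > 0]
        if len(occ) < 2:
            raise ValueError("cannot compute thresholds of a constant sequence")
        mid = 0.5 * (occ[0] + occ[1])
        low, high = mid, mid
    else:
        weights = np.log1p(counts) if params.histogram_weighting == "log" else counts
        low, high = threshold_multiotsu(classes=3, hist=(weights, centers))
    f = params.threshold_fraction
    return float(low) * f, float(high) * f


def hysteresis_mask(
    intensities: np.ndarray | VolumeStack,
    low: float,
    high: float,
    connectivity: int = 26,
) -> np.ndarray:
    """Binary foreground mask by double (hysteresis) thresholding.

    The mask is the union of connected components of ``{v >= low}`` that
    contain at least one voxel with ``v >= high``: voxels between the two
    levels survive only when attached to a bright core.

    With ``low == high`` this reduces exactly to simple thresholding.
    """
    if low > high:
        raise ValueError(f"low ({low}) must be <= high ({high})")
    v = intensities.intensities if isinstance(intensities, VolumeStack) else np.asarray(intensities)
    squeeze = False
    if v.ndim == 1:
        v = v[:, np.newaxis, np.newaxis]
        squeeze = True
    loose = v >= low
    labels, n = ndimage.label(loose, structure=_structure(connectivity))
    if n == 0:
        mask = np.zeros_like(loose)
    else:
        seeded = np.unique(labels[v >= high])
        seeded = seeded[seeded > 0]
        keep = np.zeros(n + 1, dtype=bool)
        keep[seeded] = True
        mask = keep[labels]
    return mask[:, 0, 0] if squeeze else mask


def label_regions(
    mask: np.ndarray,
    connectivity: int = 26,
    intensities: np.ndarray | None = None,
    time_index: int = 0,
) -> tuple[LabeledStack, list[RegionRecord]]:
    """Connected-component labelling with per-object geometry records.

    Centroids are unweighted voxel means (``(x, y, z)`` order); volume is the
    voxel count; ``mean_intensity`` requires ``intensities`` (NaN otherwise).
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    stack = LabeledStack(labels, time_index=time_index)
    records = _records_from_labels(stack, intensities)
    return stack, records


def _records_from_labels(stack: LabeledStack, intensities: np.ndarray | None) -> list[RegionRecord]:
    labels = stack.labels
    n = stack.n_objects
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    slices = ndimage.find_objects(labels)
    volumes = ndimage.sum_labels(np.ones_like(labels, dtype=np.int64), labels, idx)
    coms = ndimage.center_of_mass(np.ones(labels.shape), labels, idx)
    if intensities is not None:
        means = ndimage.mean(np.asarray(intensities), labels, idx)
    else:
        means = [float("nan")] * n
    records = []
    for i, lab in enumerate(idx):
        sl = slices[lab - 1]
        cy, cx, cz = coms[i]
        records.append(
            RegionRecord(
                label=int(lab),
                centroid=(float(cx), float(cy), float(cz)),
                volume=int(volumes[i]),
                mean_intensity=float(means[i]),
                bbox=(sl[0].start, sl[0].stop, sl[1].start, sl[1].stop, sl[2].start, sl[2].stop),
                time_index=stack.time_index,
            )
        )
    return records


def segment_stack(
    stack: VolumeStack,
    low: float,
    high: float,
    params: SegmentationParams | None = None,
) -> tuple[LabeledStack, list[RegionRecord]]:
    """Hysteresis-threshold one stack and label the resulting objects."""
    params = params or SegmentationParams()
    mask = hysteresis_mask(stack.intensities, low, high, params.connectivity)
    return label_regions(
        mask, params.connectivity, intensities=stack.intensities, time_index=stack.time_index
    )


def segment_sequence(
    seq: VolumeSequence,
    params: SegmentationParams | None = None,
) -> list[tuple[LabeledStack, list[RegionRecord]]]:
    """Segment every time point of a sequence.

    Thresholds are taken from ``params`` when set explicitly, otherwise from
    the pooled 3-class Otsu of the whole sequence (or per time point when
    ``params.per_timepoint_otsu``).
    """
    params = params or SegmentationParams()
    out = []
    if params.low_threshold is not None and params.high_threshold is not None:
        fixed = (params.low_threshold, params.high_threshold)
    elif params.per_timepoint_otsu:
        fixed = None
    else:
        fixed = auto_thresholds(seq, params)
    for stack in seq.stacks:
        low, high = fixed if fixed is not None else auto_thresholds(stack, params)
        out.append(segment_stack(stack, low, high, params))
    return out


def split_volume_outliers(
    labeled_seq: list[tuple[LabeledStack, list[RegionRecord]]],
    params: SegmentationParams | None = None,
    intensity_stacks: Sequence[VolumeStack] | None = None,
) -> list[tuple[LabeledStack, list[RegionRecord]]]:
    """Split objects whose volume is a pooled-distribution outlier.

    The volume mean and standard deviation are pooled over every object at
    every time point.  Each object with volume > mean + ``outlier_k``.std is
    eroded with a 3x3x3 element (or 3x3x1 when ``erode_in_plane``) until it
    separates into >= 2 components; every original voxel is then reassigned
    to the nearest surviving component so total volume is conserved.  An
    outlier that erodes away before separating is left intact and flagged
    ``unsplittable``.  Labels are refreshed to stay consecutive.
    """
    params = params or SegmentationParams()
    all_volumes = [r.volume for _, recs in labeled_seq for r in recs]
    if len(all_volumes) < 2:
        return labeled_seq
    mean = float(np.mean(all_volumes))
    std = float(np.std(all_volumes))
    cutoff = mean + params.outlier_k * std

    if params.erode_in_plane:
        erode_struct = np.ones((3, 3, 1), dtype=bool)
    else:
        erode_struct = np.ones((3, 3, 3), dtype=bool)
    conn_struct = _structure(params.connectivity)

    out = []
    for ti, (lstack, recs) in enumerate(labeled_seq):
        outliers = [r for r in recs if r.volume > cutoff]
        if not outliers:
            out.append((lstack, recs))
            continue
        labels = lstack.labels.copy()
        next_label = int(labels.max())
        unsplittable: set[int] = set()
        split_parents: dict[int, int] = {}
        for rec in outliers:
            obj = labels == rec.label
            pieces = _erode_until_split(obj, erode_struct, conn_struct)
            if pieces is None:
                unsplittable.add(rec.label)
                continue
            assignment = _assign_to_nearest(obj, pieces)
            # keep original label for piece 1, new labels for the rest
            for k in range(2, int(assignment.max()) + 1):
                next_label += 1
                labels[(assignment == k)] = next_label
                split_parents[next_label] = rec.label
            split_parents[rec.label] = rec.label
        # relabel consecutively, preserving order
        relabeled, old_of_new = _compact_labels(labels)
        new_stack = LabeledStack(relabeled, time_index=lstack.time_index)
        intens = intensity_stacks[ti].intensities if intensity_stacks is not None else None
        new_recs = _records_from_labels(new_stack, intens)
        for r in new_recs:
            old = old_of_new[r.label]
            if old in split_parents:
                r.split_from = split_parents[old]
            if old in unsplittable:
                r.unsplittable = True
        out.append((new_stack, new_recs))
    return out


def _erode_until_split(obj: np.ndarray, erode_struct, conn_struct) -> np.ndarray | None:
    """Erode ``obj`` until it falls into >=2 components; None if it vanishes."""
    cur = obj
    while True:
        cur = ndimage.binary_erosion(cur, structure=erode_struct)
        if not cur.any():
            return None
        lab, n = ndimage.label(cur, structure=conn_struct)
        if n >= 2:
            return lab


def _assign_to_nearest(obj: np.ndarray, pieces: np.ndarray) -> np.ndarray:
    """Assign every voxel of ``obj`` to the nearest eroded piece (EDT)."""
    _, (iy, ix, iz) = ndimage.distance_transform_edt(pieces == 0, return_indices=True)
    nearest = pieces[iy, ix, iz]
    return np.where(obj, nearest, 0)


def _compact_labels(labels: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    old_of_new: dict[int, int] = {}
    for new, old in enumerate(present, start=1):
        lut[old] = new
        old_of_new[new] = int(old)
    return lut[labels], old_of_new
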