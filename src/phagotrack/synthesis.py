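"""Synthetic fluorescence benchmark: moving Gaussian cells with known tracks.

The generator renders 3D stacks of bright Gaussian-blob cells travelling
along parametric paths over a flat background, together with the exact
("gold standard") centroids, so segmentation and tracking accuracy can be
measured.  The default configuration emulates a wound-response recording:
98 time points of 11 slices of 275x275 pixels with six cells whose paths
cover the conditions that make tracking hard — straight runs, tortuous
(sinusoidal) wander, delayed activation, close mutual proximity (a crossing
pair) and near-stationary dwelling.

Noise is added either as white Gaussian noise or as a Poisson + Gaussian
mixture (the better model of photon-counting microscopy noise).  Noise
levels are calibrated by bisection so that the Bhattacharyya distance (BD)
between the cell and background intensity classes hits prescribed
separability values; the five default levels target the
reference separability ladder BD = (1.61, 1.25, 1.0, 0.66, 0.45).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .volume_io import VolumeStack, VolumeSequence

#: Separability ladder of the five default noise levels (most to least
#: separable), expressed as Bhattacharyya distances.
DEFAULT_BD_LEVELS = (1.61, 1.25, 1.0, 0.66, 0.45)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic benchmark.

    ``amplitude`` is the per-cell peak intensity above the flat background;
    a tuple assigns cells different brightnesses (cycled when shorter than
    ``n_cells``), emulating the mix of bright and faint cells seen in real
    recordings.  Rendered intensities are clipped at ``saturation``,
    emulating detector saturation in the bright cell cores (a flat-topped
    core also makes segmentation robust to upward rescaling of the high
    threshold, as in real recordings).  Cell extent
    is set by the Gaussian widths ``sigma_xy`` (in-plane; the anisotropic
    shape stretches this by ``anisotropy`` along a per-cell orientation) and
    ``sigma_z``.  Each cell's profile is truncated at ``class_fraction`` of
    its peak; the region above that cut is the cell's gold-standard extent
    (its "class region", whose voxel count is the gold volume).  Including
    the dim fringes in the cell class gives the class the large internal
    intensity spread seen in real fluorescence recordings, where the
    cell/background separability is limited by the dim cell parts rather
    than by the bright cores.  ``volume_growth`` programs a linear relative
    volume increase per image column (0 = constant volume), used for
    volume-recovery experiments.
    """

    n_cells: int = 6
    n_timepoints: int = 98
    rows: int = 275
    cols: int = 275
    slices: int = 11
    shape: str = "anisotropic_gaussian"  # or "irregular"
    amplitude: float | tuple = 250.0
    background: float = 8.0
    saturation: float | None = 230.0
    sigma_xy: float = 3.0
    sigma_z: float = 1.2
    anisotropy: float = 1.6
    noise_model: str = "white_gaussian"  # or "poisson_gaussian"
    noise_sigma: float = 0.0
    class_fraction: float = 0.05
    volume_growth: float = 0.0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_interval: float = 0.5
    paths: list | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rows, self.cols, self.slices, self.n_timepoints, self.n_cells) <= 0:
            raise ValueError("all dimensions must be > 0")
        if min(self.amplitudes) <= self.background:
            raise ValueError("every amplitude must exceed the background mean")
        if self.shape not in ("anisotropic_gaussian", "irregular"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.noise_model not in ("white_gaussian", "poisson_gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not 0 < self.class_fraction < 1:
            raise ValueError("class_fraction must lie in (0, 1)")
        if self.saturation is not None and self.saturation <= self.background:
            raise ValueError("saturation must exceed the background mean")
        extent = self.reach_sigmas * self.sigma_xy * max(self.anisotropy, 1.0)
        if 2 * extent >= min(self.rows, self.cols):
            raise ValueError("cells are larger than the field")

    @property
    def reach_sigmas(self) -> float:
        """Blob radius (in widths) of the class-fraction isosurface."""
        return math.sqrt(2.0 * math.log(1.0 / self.class_fraction))

    @property
    def amplitudes(self) -> list[float]:
        """Per-cell peak amplitudes (cycled to ``n_cells``)."""
        amp = self.amplitude if isinstance(self.amplitude, (tuple, list)) else (self.amplitude,)
        return [float(amp[i % len(amp)]) for i in range(self.n_cells)]


@dataclass
class GoldStandard:
    """Exact per-cell trajectories, volumes and class masks.

    ``table`` has one row per cell per time point with columns
    ``cell_id, t, x, y, z, volume``; volume is the voxel count of the cell's
    rendered class region (everything above ``class_fraction`` of its peak).
    ``masks`` holds one boolean array per time point marking the union of
    those regions — the "cell class" used for separability (BD/SNR)
    statistics; everything else is background.
    """

    table: pd.DataFrame
    masks: list[np.ndarray] | None = None

    def cell_track(self, cell_id: int) -> pd.DataFrame:
        return self.table[self.table["cell_id"] == cell_id].sort_values("t")

    @property
    def n_cells(self) -> int:
        return int(self.table["cell_id"].nunique())


@dataclass
class ClassStats:
    """Mean/variance summary of one voxel-intensity class."""

    mean: float
    variance: float
    count: int

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.count < 2:
            raise ValueError("a class needs at least 2 samples")

    @classmethod
    def from_voxels(cls, voxels: np.ndarray) -> "ClassStats":
        v = np.asarray(voxels, dtype=np.float64).ravel()
        return cls(float(v.mean()), float(v.var()), int(v.size))


# ---------------------------------------------------------------------------
# paths

def _lerp(a, b, f):
    return a + (b - a) * f


def straight_path(p0, p1, n_t: int, activation: int = 0) -> np.ndarray:
    """Linear motion from p0 to p1; idle at p0 before ``activation``."""
    out = np.empty((n_t, 3))
    span = max(n_t - 1 - activation, 1)
    for t in range(n_t):
        f = 0.0 if t <= activation else (t - activation) / span
        out[t] = _lerp(np.asarray(p0, float), np.asarray(p1, float), f)
    return out


def sinusoid_path(p0, p1, n_t: int, amplitude: float = 20.0, cycles: float = 3.0) -> np.ndarray:
    """Tortuous motion: straight drift with a sinusoidal lateral wobble."""
    base = straight_path(p0, p1, n_t)
    tau = np.linspace(0.0, 1.0, n_t)
    direction = np.asarray(p1, float)[:2] - np.asarray(p0, float)[:2]
    norm = np.linalg.norm(direction)
    if norm == 0:
        lateral = np.array([0.0, 1.0])
    else:
        d = direction / norm
        lateral = np.array([-d[1], d[0]])
    wobble = amplitude * np.sin(2 * math.pi * cycles * tau)
    base[:, 0] += lateral[0] * wobble
    base[:, 1] += lateral[1] * wobble
    return base


def default_paths(spec: SyntheticSpec) -> list[np.ndarray]:
    """The benchmark path library scaled to the field dimensions.

    Styles cycled over cells: straight run, tortuous sinusoid, delayed
    activation, a crossing pair (minimum mutual distance below one cell
    diameter at the crossing frame, separated mostly in z), and a
    near-stationary dweller.
    """
    n_t = spec.n_timepoints
    w, h, d = spec.cols, spec.rows, spec.slices
    m = 0.09  # margin as a fraction of the field
    x0, x1 = m * w, (1 - m) * w
    zmid = (d - 1) / 2.0
    makers: list[Callable[[], np.ndarray]] = [
        lambda: straight_path((x0, 0.14 * h, zmid), (x1, 0.20 * h, zmid), n_t),
        lambda: sinusoid_path((x0, 0.36 * h, zmid), (x1, 0.33 * h, zmid), n_t,
                              amplitude=0.07 * h, cycles=3.0),
        lambda: straight_path((0.13 * w, 0.58 * h, max(zmid - 1, 0)),
                              (x1, 0.62 * h, max(zmid - 1, 0)), n_t,
                              activation=n_t // 3),
        lambda: straight_path((x0, 0.75 * h, max(zmid - 2.5, 0)),
                              (x1, 0.89 * h, max(zmid - 2.5, 0)), n_t),
        lambda: straight_path((x0, 0.89 * h, min(zmid + 2.5, d - 1)),
                              (x1, 0.75 * h, min(zmid + 2.5, d - 1)), n_t),
        lambda: straight_path((0.76 * w, 0.44 * h, zmid), (0.87 * w, 0.47 * h, zmid), n_t),
    ]
    return [makers[i % len(makers)]() for i in range(spec.n_cells)]


# ---------------------------------------------------------------------------
# rendering

def _cell_scales(spec: SyntheticSpec, xs: np.ndarray) -> np.ndarray:
    """Per-position width multiplier implementing the programmed volume trend.

    Cell volume scales with the cube of the width multiplier, so a linear
    relative volume trend ``1 + volume_growth * column`` needs the cube root.
    """
    if spec.volume_growth == 0.0:
        return np.ones_like(xs)
    rel = np.maximum(1.0 + spec.volume_growth * xs, 0.05)
    return np.cbrt(rel)


def _render_cell_patch(spec: SyntheticSpec, center, scale: float, theta: float,
                       sub_offsets: np.ndarray | None, amplitude: float):
    """Render one cell's intensity patch; returns (y0, x0, z0, patch)."""
    cx, cy, cz = center
    s_major = spec.sigma_xy * (spec.anisotropy if spec.shape == "anisotropic_gaussian" else 1.0) * scale
    s_minor = spec.sigma_xy * scale
    s_z = spec.sigma_z * scale
    k = spec.reach_sigmas
    reach_xy = k * max(s_major, s_minor) + (0.0 if sub_offsets is None else float(np.abs(sub_offsets).max()))
    reach_z = k * s_z
    y0 = max(int(math.floor(cy - reach_xy)), 0)
    y1 = min(int(math.ceil(cy + reach_xy)) + 1, spec.rows)
    x0 = max(int(math.floor(cx - reach_xy)), 0)
    x1 = min(int(math.ceil(cx + reach_xy)) + 1, spec.cols)
    z0 = max(int(math.floor(cz - reach_z)), 0)
    z1 = min(int(math.ceil(cz + reach_z)) + 1, spec.slices)
    if y0 >= y1 or x0 >= x1 or z0 >= z1:
        return y0, x0, z0, np.zeros((0, 0, 0), dtype=np.float32)
    yy, xx, zz = np.meshgrid(
        np.arange(y0, y1, dtype=np.float64),
        np.arange(x0, x1, dtype=np.float64),
        np.arange(z0, z1, dtype=np.float64),
        indexing="ij",
    )
    zq = (zz - cz) ** 2 / (2 * s_z ** 2)
    if sub_offsets is None:
        ct, st = math.cos(theta), math.sin(theta)
        u = ct * (xx - cx) + st * (yy - cy)
        v = -st * (xx - cx) + ct * (yy - cy)
        blob = np.exp(-(u ** 2 / (2 * s_major ** 2) + v ** 2 / (2 * s_minor ** 2) + zq))
    else:
        # irregular shape: base isotropic blob plus six shifted sub-blobs
        blob = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s_minor ** 2) - zq)
        s_sub = s_minor / 1.5
        for ox, oy in sub_offsets:
            blob += 0.5 * np.exp(
                -((xx - cx - ox * scale) ** 2 + (yy - cy - oy * scale) ** 2) / (2 * s_sub ** 2) - zq
            )
        blob /= blob.max()
    blob = np.where(blob >= spec.class_fraction, blob, 0.0)  # hard cut = class edge
    return y0, x0, z0, (amplitude * blob).astype(np.float32)


def generate_dataset(spec: SyntheticSpec, seed: int | None = None) -> tuple[VolumeSequence, GoldStandard]:
    """Render the noiseless benchmark and its gold-standard tracks.

    Per-cell intensity profiles (anisotropic Gaussians with per-cell
    orientation, or irregular blobs made of a base isotropic Gaussian plus
    six randomly shifted sub-Gaussians) are summed over a flat background at
    the path positions.  The gold standard records the exact path centroids
    and the voxel count of each cell's half-maximum region.  Noise is added
    separately (:func:`add_noise`).
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    paths = spec.paths if spec.paths is not None else default_paths(spec)
    if len(paths) != spec.n_cells:
        raise ValueError(f"got {len(paths)} paths for {spec.n_cells} cells")
    thetas = rng.uniform(0, math.pi, size=spec.n_cells)
    amps = spec.amplitudes
    sub_offsets = None
    if spec.shape == "irregular":
        sub_offsets = rng.uniform(-spec.sigma_xy, spec.sigma_xy, size=(spec.n_cells, 6, 2))

    stacks = []
    masks = []
    gold_rows = []
    for t in range(spec.n_timepoints):
        vol = np.full((spec.rows, spec.cols, spec.slices), spec.background, dtype=np.float32)
        mask = np.zeros((spec.rows, spec.cols, spec.slices), dtype=bool)
        for c in range(spec.n_cells):
            center = paths[c][t]
            scale = float(_cell_scales(spec, np.array([center[0]]))[0])
            offs = sub_offsets[c] if sub_offsets is not None else None
            y0, x0, z0, patch = _render_cell_patch(spec, center, scale, thetas[c], offs, amps[c])
            if patch.size == 0:
                raise ValueError(f"cell {c} leaves the field at t={t}")
            sl = (slice(y0, y0 + patch.shape[0]), slice(x0, x0 + patch.shape[1]),
                  slice(z0, z0 + patch.shape[2]))
            vol[sl] += patch
            cell_region = patch > 0
            mask[sl] |= cell_region
            gold_rows.append(
                dict(cell_id=c, t=t, x=float(center[0]), y=float(center[1]),
                     z=float(center[2]), volume=int(np.count_nonzero(cell_region)))
            )
        if spec.saturation is not None:
            np.minimum(vol, spec.saturation, out=vol)
        stacks.append(VolumeStack(vol, time_index=t, voxel_size=spec.voxel_size,
                                  frame_interval=spec.frame_interval))
        masks.append(mask)
    seq = VolumeSequence.from_stacks(stacks)
    gold = GoldStandard(pd.DataFrame(gold_rows), masks=masks)
    return seq, gold


def add_noise(seq: VolumeSequence, model: str = "white_gaussian", sigma: float = 0.0,
              seed: int = 0) -> VolumeSequence:
    """Corrupt a sequence with calibratable noise.

    ``white_gaussian`` adds i.i.d. N(0, sigma^2) to every voxel;
    ``poisson_gaussian`` replaces each voxel's value by a Poisson draw with
    that expectation (photon shot noise) and then adds N(0, sigma^2) read
    noise.  Results are clipped below at 0, the valid range of intensity
    data (quantisation to the export bit depth happens only on write).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if model not in ("white_gaussian", "poisson_gaussian"):
        raise ValueError(f"unknown noise model {model!r}")
    if sigma == 0.0 and model == "white_gaussian":
        return seq
    rng = np.random.default_rng(seed)
    out = []
    for stack in seq.stacks:
        v = stack.intensities.astype(np.float32)
        if model == "poisson_gaussian":
            v = rng.poisson(np.maximum(v, 0)).astype(np.float32)
        if sigma > 0:
            v = v + rng.normal(0.0, sigma, size=v.shape).astype(np.float32)
        out.append(replace(stack, intensities=np.maximum(v, 0.0)))
    return VolumeSequence.from_stacks(out, source_layout=seq.source_layout)


# ---------------------------------------------------------------------------
# separability

def bhattacharyya_distance(a: ClassStats, b: ClassStats) -> float:
    """Bhattacharyya distance between two intensity classes.

    Computed from class means and variances:
    ``BD = 1/4 ln(1/4 (s_a/s_b + s_b/s_a + 2)) + 1/4 (m_a - m_b)^2 / (s_a + s_b)``.
    Symmetric, non-negative, 0 iff the stats coincide; larger values mean
    more separable classes.
    """
    if a.variance <= 0 or b.variance <= 0:
        raise ValueError("Bhattacharyya distance requires strictly positive variances")
    ratio = a.variance / b.variance
    term1 = 0.25 * math.log(0.25 * (ratio + 1.0 / ratio + 2.0))
    term2 = 0.25 * (a.mean - b.mean) ** 2 / (a.variance + b.variance)
    return term1 + term2


def snr_db(signal: ClassStats | np.ndarray, background: ClassStats | np.ndarray) -> float:
    """Signal-to-noise ratio in dB: 20 log10(RMS_signal / RMS_background).

    The RMS of a class is the root mean squared deviation of its voxel
    intensities from the class average.
    """
    s = signal if isinstance(signal, ClassStats) else ClassStats.from_voxels(signal)
    b = background if isinstance(background, ClassStats) else ClassStats.from_voxels(background)
    rms_b = math.sqrt(b.variance)
    if rms_b == 0:
        raise ValueError("background RMS is zero; SNR undefined")
    return 20.0 * math.log10(math.sqrt(s.variance) / rms_b)


def _resolve_masks(masks) -> list[np.ndarray]:
    if isinstance(masks, GoldStandard):
        if masks.masks is None:
            raise ValueError("GoldStandard carries no class masks")
        return masks.masks
    return list(masks)


def empirical_class_stats(
    noisy_seq: VolumeSequence,
    masks,
) -> tuple[ClassStats, ClassStats]:
    """Cell/background class statistics of a (possibly noisy) sequence.

    The cell class is the union of the gold-standard cell regions
    (``masks``: a :class:`GoldStandard` or one boolean array per time
    point); the background class is everything else.  Statistics stream over
    time points so no full-volume copy is held.
    """
    masks = _resolve_masks(masks)
    sums = np.zeros(2)
    sqs = np.zeros(2)
    counts = np.zeros(2, dtype=np.int64)
    for noisy, mask in zip(noisy_seq.stacks, masks):
        for i, sel in enumerate((mask, ~mask)):
            v = noisy.intensities[sel].astype(np.float64)
            sums[i] += v.sum()
            sqs[i] += np.square(v).sum()
            counts[i] += v.size
    stats = []
    for i in range(2):
        mean = sums[i] / counts[i]
        var = sqs[i] / counts[i] - mean ** 2
        stats.append(ClassStats(float(mean), float(max(var, 0.0)), int(counts[i])))
    return stats[0], stats[1]


def class_value_histograms(seq: VolumeSequence, masks, n_bins: int = 512):
    """Per-class histograms of noiseless voxel values (for the noise model).

    Returns ``((values, probs) cell, (values, probs) background)`` where
    ``probs`` sum to 1 within each class.
    """
    masks = _resolve_masks(masks)
    lo = min(float(s.intensities.min()) for s in seq.stacks)
    hi = max(float(s.intensities.max()) for s in seq.stacks)
    hi = max(hi, lo + 1e-6)
    counts = [np.zeros(n_bins, dtype=np.int64), np.zeros(n_bins, dtype=np.int64)]
    for stack, mask in zip(seq.stacks, masks):
        for i, sel in enumerate((mask, ~mask)):
            h, edges = np.histogram(stack.intensities[sel], bins=n_bins, range=(lo, hi))
            counts[i] += h
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = []
    for c in counts:
        nz = c > 0
        out.append((centers[nz], c[nz] / c.sum()))
    return out[0], out[1]


def _clipped_normal_moments(values: np.ndarray, probs: np.ndarray, sigma: float):
    """Mean/variance of max(v + N(0, sigma^2), 0) for v ~ (values, probs)."""
    if sigma == 0.0:
        m = float(np.dot(probs, values))
        m2 = float(np.dot(probs, values ** 2))
        return m, max(m2 - m * m, 0.0)
    from scipy.stats import norm

    a = values / sigma
    phi = norm.pdf(a)
    Phi = norm.cdf(a)
    ey = values * Phi + sigma * phi
    ey2 = (values ** 2 + sigma ** 2) * Phi + values * sigma * phi
    m = float(np.dot(probs, ey))
    m2 = float(np.dot(probs, ey2))
    return m, max(m2 - m * m, 0.0)


def predicted_class_stats(hists, sigma: float, model: str = "white_gaussian"):
    """Model cell/background stats after noise of strength ``sigma``.

    For white Gaussian noise the zero-clipping of intensities is modelled
    exactly (clipped-normal moments averaged over the noiseless value
    histogram of each class); for Poisson + Gaussian noise the variance is
    the unclipped ``value + sigma^2`` (clipping is negligible at realistic
    photon counts).
    """
    (sv, sp), (bv, bp) = hists
    out = []
    for values, probs in ((sv, sp), (bv, bp)):
        if model == "white_gaussian":
            m, var = _clipped_normal_moments(values, probs, sigma)
        else:
            m = float(np.dot(probs, values))
            ev2 = float(np.dot(probs, values ** 2 + values)) + sigma ** 2
            var = max(ev2 - m * m, 0.0)
        out.append(ClassStats(m, max(var, 1e-12), max(len(values), 2)))
    return out[0], out[1]


def predicted_bd(hists, sigma: float, model: str = "white_gaussian") -> float:
    """Model BD of the dataset after adding noise of strength ``sigma``."""
    sig, bg = predicted_class_stats(hists, sigma, model)
    return bhattacharyya_distance(sig, bg)


def _spec_key(spec: SyntheticSpec) -> tuple:
    parts = []
    for name, val in vars(spec).items():
        if name == "paths":
            val = None if val is None else tuple(np.asarray(p, float).tobytes() for p in val)
        elif isinstance(val, (list, tuple)):
            val = tuple(val)
        parts.append((name, val))
    return tuple(parts)


def noiseless_class_histograms(spec: SyntheticSpec, seed: int | None = None,
                               _cache: dict = {}):
    """Per-class value histograms of the rendered noiseless dataset (memoised)."""
    key = (_spec_key(spec), spec.seed if seed is None else seed)
    if key not in _cache:
        seq, gold = generate_dataset(spec, seed)
        _cache[key] = class_value_histograms(seq, gold)
    return _cache[key]


def calibrate_noise(
    spec: SyntheticSpec,
    target_bd: float,
    tolerance: float = 1e-4,
    seed: int | None = None,
) -> float:
    """Noise sigma whose model-predicted BD hits ``target_bd``.

    Added noise widens both class distributions while the zero-clip keeps
    them valid intensities; the predicted BD (clipped-noise model evaluated
    on the noiseless per-class value histograms) decreases monotonically
    with sigma, so plain bisection finds the calibrated level
    deterministically.

    Raises
    ------
    ValueError
        If the target exceeds the noiseless BD (unattainable); the message
        reports the attainable range.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    hists = noiseless_class_histograms(spec, seed)
    bd0 = predicted_bd(hists, 0.0, spec.noise_model)
    if target_bd >= bd0:
        if math.isclose(target_bd, bd0, rel_tol=1e-12):
            return 0.0
        raise ValueError(
            f"target BD {target_bd} is unattainable: the noiseless dataset has BD "
            f"{bd0:.4f}; attainable range is (0, {bd0:.4f})"
        )
    if target_bd <= 0:
        raise ValueError("target BD must be > 0")
    lo, hi = 0.0, 1.0
    while predicted_bd(hists, hi, spec.noise_model) > target_bd:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("bisection bracket expansion failed")
    while True:
        mid = 0.5 * (lo + hi)
        bd = predicted_bd(hists, mid, spec.noise_model)
        if abs(bd - target_bd) <= tolerance:
            return mid
        if bd > target_bd:
            lo = mid
        else:
            hi = mid


def calibrated_noise_levels(
    spec: SyntheticSpec | None = None,
    targets: Sequence[float] = DEFAULT_BD_LEVELS,
    tolerance: float = 1e-4,
) -> list[float]:
    """Noise sigmas calibrated to the default separability ladder.

    Recomputed by bisection at call time from the rendered noiseless dataset,
    so the shipped levels are reproducible rather than hard-coded.
    """
    spec = spec or SyntheticSpec()
    return [calibrate_noise(spec, bd, tolerance) for bd in targets]
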