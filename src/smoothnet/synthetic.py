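"""Synthetic multi-subject voxel cohorts with distance-dependent ROI coupling.

The generator emulates the statistical structure that ROI-level functional
connectivity analyses assume of resting-state BOLD data: a two-hemisphere
voxel lattice partitioned into contiguous regions of widely varying size,
region-to-region coupling that decays with centroid distance, elevated
coupling between homotopic (mirror-hemisphere) region pairs, and independent
Gaussian noise added to each voxel on top of its region's latent signal.

Every quantity is deterministic given the seed, so downstream network
analyses are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from collections import deque
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "Parcellation",
    "CohortSpec",
    "VoxelTimeSeriesSet",
    "generate_parcellation",
    "generate_cohort",
    "target_correlation_matrix",
    "nearest_correlation",
    "drop_initial_frames",
]

#: face (6-) connectivity offsets used by region growing
_NEIGHBOR_OFFSETS = (
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
)


@dataclass(eq=False)
class Parcellation:
    """Voxel-to-ROI label map on a 3-D grid with millimetre geometry.

    ``labels`` is a 3-D integer array over the acquisition grid: 0 marks
    out-of-mask voxels, in-mask voxels carry exactly one ROI id in
    ``1..n_rois``.  ``homotopic_pairs`` lists (left_id, right_id) ROI pairs
    that mirror each other across the inter-hemispheric plane.

    Voxel centers sit at ``(index + 0.5) * voxel_size_mm`` per axis
    (0-based indices); users with a NIfTI affine can override centroids by
    transforming indices themselves before building geometry.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    labels: NDArray[np.integer]
    homotopic_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != self.grid_shape:
            raise ValueError(
                f"labels shape {self.labels.shape} != grid_shape {self.grid_shape}"
            )
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = outside mask)")
        n = int(self.labels.max())
        if n < 1:
            raise ValueError("parcellation has no ROIs")
        counts = np.bincount(self.labels.ravel(), minlength=n + 1)[1:]
        if (counts == 0).any():
            missing = np.flatnonzero(counts == 0) + 1
            raise ValueError(f"ROI ids missing from label map: {missing.tolist()}")
        seen: set[int] = set()
        for a, b in self.homotopic_pairs:
            if a in seen or b in seen or a == b:
                raise ValueError("homotopic pairs must be disjoint")
            seen.update((a, b))

    # -- derived geometry -------------------------------------------------

    @property
    def n_rois(self) -> int:
        return int(self.labels.max())

    @cached_property
    def mask(self) -> NDArray[np.bool_]:
        return self.labels > 0

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @cached_property
    def voxel_indices(self) -> NDArray[np.int64]:
        """In-mask voxel grid indices, C-order; defines the series row order."""
        return np.argwhere(self.mask)

    @cached_property
    def voxel_labels(self) -> NDArray[np.int32]:
        """ROI id per in-mask voxel, aligned with :attr:`voxel_indices`."""
        return self.labels[self.mask]

    @cached_property
    def voxel_coords_mm(self) -> NDArray[np.float64]:
        return (self.voxel_indices + 0.5) * np.asarray(self.voxel_size_mm)

    @cached_property
    def roi_sizes(self) -> NDArray[np.int64]:
        """Voxel count per ROI (index 0 = ROI 1)."""
        return np.bincount(self.voxel_labels, minlength=self.n_rois + 1)[1:]

    @cached_property
    def centroids_mm(self) -> NDArray[np.float64]:
        cent = np.zeros((self.n_rois, 3))
        np.add.at(cent, self.voxel_labels - 1, self.voxel_coords_mm)
        return cent / self.roi_sizes[:, None]


@dataclass(frozen=True)
class CohortSpec:
    """Statistical parameters of a synthetic cohort.

    coupling_scale_mm
        e-folding length of the exponential distance decay of latent
        ROI-ROI correlation.
    homotopic_boost
        additive correlation bonus for mirror-hemisphere ROI pairs, in [0, 1).
    voxel_noise_sd
        standard deviation of i.i.d. Gaussian noise added per voxel on top
        of the unit-variance latent ROI signal (0 = noise-free voxels).
    subject_variation_sd
        standard deviation of the symmetric perturbation applied to the
        latent correlation matrix per subject before re-projection.
    """

    n_subjects: int = 13
    n_timepoints: int = 212
    coupling_scale_mm: float = 30.0
    homotopic_boost: float = 0.25
    voxel_noise_sd: float = 1.0
    subject_variation_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_timepoints < 1:
            raise ValueError("cohort needs at least one subject and one timepoint")
        if self.coupling_scale_mm <= 0:
            raise ValueError("coupling_scale_mm must be positive")
        if not 0 <= self.homotopic_boost < 1:
            raise ValueError("homotopic_boost must be in [0, 1)")
        if self.voxel_noise_sd < 0 or self.subject_variation_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass(eq=False)
class VoxelTimeSeriesSet:
    """One scalar series per in-mask voxel (rows follow parcellation order).

    ``latent_roi_series`` holds the generator's noise-free per-ROI signals
    (R x T) when the set came from :func:`generate_cohort`; it is ``None``
    for data loaded from disk.
    """

    parcellation: Parcellation
    series: NDArray[np.float64]
    latent_roi_series: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=np.float64)
        if self.series.ndim != 2 or self.series.shape[0] != self.parcellation.n_voxels:
            raise ValueError(
                f"series must be (n_voxels, T) = ({self.parcellation.n_voxels}, T); "
                f"got {self.series.shape}"
            )
        if not np.isfinite(self.series).all():
            raise ValueError("voxel series contain non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


# ---------------------------------------------------------------------------
# parcellation generation
# ---------------------------------------------------------------------------


def _farthest_point_seeds(
    coords: NDArray[np.float64], k: int, rng: np.random.Generator
) -> list[int]:
    """First seed random, remaining seeds greedily maximize min-distance."""
    n = len(coords)
    first = int(rng.integers(n))
    seeds = [first]
    d2 = np.einsum("ij,ij->i", coords - coords[first], coords - coords[first])
    for _ in range(k - 1):
        nxt = int(np.argmax(d2))
        if d2[nxt] == 0.0:
            raise ValueError("grid too small to host the requested number of ROIs")
        seeds.append(nxt)
        delta = coords - coords[nxt]
        d2 = np.minimum(d2, np.einsum("ij,ij->i", delta, delta))
    return seeds


def _integer_targets(raw: NDArray[np.float64], total: int) -> NDArray[np.int64]:
    """Largest-remainder apportionment of `total` voxels, each ROI >= 1."""
    share = raw / raw.sum() * total
    base = np.floor(share).astype(np.int64)
    rem = total - int(base.sum())
    order = np.argsort(-(share - base), kind="stable")
    base[order[:rem]] += 1
    base = np.maximum(base, 1)
    # max(...,1) may overshoot the total; shave from the largest entries
    while base.sum() > total:
        base[int(np.argmax(base))] -= 1
    return base


def _grow_regions(
    half_shape: tuple[int, int, int],
    seeds: list[tuple[int, int, int]],
    targets: NDArray[np.int64],
) -> NDArray[np.int32]:
    """Multi-source region growing with size-proportional scheduling.

    At each step the ROI with the smallest claimed/target fraction whose
    frontier is non-empty claims one voxel (FIFO, 6-connectivity).  ROIs past
    their target keep growing only once every under-target frontier is
    exhausted, so realized sizes track targets while staying contiguous and
    covering the whole hemisphere.
    """
    k = len(seeds)
    labels = np.zeros(half_shape, dtype=np.int32)
    frontiers: list[deque[tuple[int, int, int]]] = [deque() for _ in range(k)]
    claimed = np.zeros(k, dtype=np.int64)

    def push_neighbors(r: int, idx: tuple[int, int, int]) -> None:
        x, y, z = idx
        for dx, dy, dz in _NEIGHBOR_OFFSETS:
            nx_, ny_, nz_ = x + dx, y + dy, z + dz
            if (
                0 <= nx_ < half_shape[0]
                and 0 <= ny_ < half_shape[1]
                and 0 <= nz_ < half_shape[2]
                and labels[nx_, ny_, nz_] == 0
            ):
                frontiers[r].append((nx_, ny_, nz_))

    for r, s in enumerate(seeds):
        labels[s] = r + 1
        claimed[r] = 1
        push_neighbors(r, s)

    remaining = int(np.prod(half_shape)) - k
    while remaining > 0:
        best, best_frac = -1, np.inf
        for r in range(k):
            if not frontiers[r]:
                continue
            frac = claimed[r] / targets[r]
            if frac < best_frac:
                best, best_frac = r, frac
        if best < 0:
            raise RuntimeError("region growing stalled with unlabeled voxels")
        fr = frontiers[best]
        claimed_one = False
        while fr:
            idx = fr.popleft()
            if labels[idx] == 0:
                labels[idx] = best + 1
                claimed[best] += 1
                remaining -= 1
                push_neighbors(best, idx)
                claimed_one = True
                break
        if not claimed_one:
            continue  # frontier was stale; rescheduling picks another ROI
    return labels


def generate_parcellation(
    grid_shape: tuple[int, int, int],
    n_rois: int,
    size_heterogeneity: float = 1.0,
    seed: int = 0,
    *,
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0),
) -> Parcellation:
    """Partition a two-hemisphere lattice into contiguous mirrored ROIs.

    The first grid axis is the left-right axis; the left half is split into
    ``n_rois/2`` contiguous regions by seeded region growing and mirrored
    onto the right half, so ROI ``r`` (left) and ``r + n_rois/2`` (right)
    are exact mirror images and form a homotopic pair.

    Parameters
    ----------
    size_heterogeneity
        Log-normal sigma of the target ROI sizes.  0 gives an equal split;
        ~1 reproduces a heavy-tailed anatomical size spread (two orders of
        magnitude between smallest and largest region).
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 1 for s in grid_shape):
        raise ValueError("grid_shape must be three positive integers")
    if n_rois < 2 or n_rois % 2:
        raise ValueError("n_rois must be an even integer >= 2 (half per hemisphere)")
    if grid_shape[0] % 2:
        raise ValueError("first grid axis must be even (two hemispheres)")
    if size_heterogeneity < 0:
        raise ValueError("size_heterogeneity must be non-negative")
    half_shape = (grid_shape[0] // 2, grid_shape[1], grid_shape[2])
    n_left = int(np.prod(half_shape))
    k = n_rois // 2
    if k > n_left:
        raise ValueError("grid too small to host the requested number of ROIs")

    rng = np.random.default_rng(seed)
    if size_heterogeneity == 0:
        raw = np.ones(k)
    else:
        raw = rng.lognormal(mean=0.0, sigma=size_heterogeneity, size=k)
    targets = _integer_targets(raw, n_left)

    coords = np.indices(half_shape).reshape(3, -1).T.astype(float)
    seed_flat = _farthest_point_seeds(coords, k, rng)
    seed_idx = [tuple(int(v) for v in coords[i]) for i in seed_flat]

    left = _grow_regions(half_shape, seed_idx, targets)
    right = np.where(left > 0, left + k, 0)[::-1, :, :]
    labels = np.concatenate([left, right], axis=0)
    pairs = tuple((r, r + k) for r in range(1, k + 1))
    return Parcellation(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        labels=labels,
        homotopic_pairs=pairs,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def nearest_correlation(m: NDArray[np.float64]) -> NDArray[np.float64]:
    """Nearest-correlation repair: clip eigenvalues at 0, rescale diag to 1."""
    sym = (m + m.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, 0.0, None)
    a = (v * w) @ v.T
    d = np.diag(a).copy()
    d[d <= 0] = 1.0
    a = a / np.sqrt(np.outer(d, d))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def target_correlation_matrix(
    parcellation: Parcellation, spec: CohortSpec
) -> NDArray[np.float64]:
    """Latent ROI-ROI correlation target: exponential distance decay plus
    a homotopic bonus, projected to the nearest correlation matrix."""
    cent = parcellation.centroids_mm
    diff = cent[:, None, :] - cent[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    c = np.exp(-dist / spec.coupling_scale_mm)
    if spec.homotopic_boost > 0:
        for a, b in parcellation.homotopic_pairs:
            c[a - 1, b - 1] += spec.homotopic_boost
            c[b - 1, a - 1] += spec.homotopic_boost
    off = ~np.eye(len(c), dtype=bool)
    c[off] = np.clip(c[off], -0.999, 0.999)
    np.fill_diagonal(c, 1.0)
    return nearest_correlation(c)


def _correlated_series(
    corr: NDArray[np.float64], n_timepoints: int, rng: np.random.Generator
) -> NDArray[np.float64]:
    """Draw zero-mean unit-variance series (R x T) with the given correlation.

    Time samples are i.i.d. Gaussian: the downstream analysis is
    correlation-based and invariant to temporal ordering, so no
    autocorrelation is modeled.
    """
    w, v = np.linalg.eigh(corr)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_timepoints, corr.shape[0]))
    return (z @ factor.T).T


def generate_cohort(
    parcellation: Parcellation, spec: CohortSpec
) -> list[VoxelTimeSeriesSet]:
    """Generate one voxel-level dataset per subject.

    Per subject: the shared latent correlation target is perturbed by a
    symmetric Gaussian of sd ``subject_variation_sd`` and re-projected to a
    correlation matrix; latent ROI series are drawn with that correlation;
    every voxel receives its ROI's latent series plus independent Gaussian
    noise of sd ``voxel_noise_sd``.  Subject ``s`` uses sub-seed
    ``seed + 1000*(s+1)``.
    """
    base = target_correlation_matrix(parcellation, spec)
    r = parcellation.n_rois
    off = ~np.eye(r, dtype=bool)
    labels0 = parcellation.voxel_labels - 1
    cohort: list[VoxelTimeSeriesSet] = []
    for s in range(spec.n_subjects):
        rng = np.random.default_rng(spec.seed + 1000 * (s + 1))
        if spec.subject_variation_sd > 0:
            e = rng.normal(0.0, spec.subject_variation_sd, size=(r, r))
            e = (e + e.T) / 2.0
            np.fill_diagonal(e, 0.0)
            c = base + e
            c[off] = np.clip(c[off], -0.999, 0.999)
            c = nearest_correlation(c)
        else:
            c = base
        latent = _correlated_series(c, spec.n_timepoints, rng)
        series = latent[labels0]
        if spec.voxel_noise_sd > 0:
            series = series + rng.normal(
                0.0, spec.voxel_noise_sd, size=(parcellation.n_voxels, spec.n_timepoints)
            )
        else:
            series = series.copy()
        cohort.append(
            VoxelTimeSeriesSet(
                parcellation=parcellation, series=series, latent_roi_series=latent
            )
        )
    return cohort


def drop_initial_frames(
    data: VoxelTimeSeriesSet | NDArray[np.float64], n_frames: int
) -> VoxelTimeSeriesSet | NDArray[np.float64]:
    """Discard the first ``n_frames`` timepoints (scanner-transient removal)."""
    if n_frames < 0:
        raise ValueError("n_frames must be non-negative")
    if isinstance(data, VoxelTimeSeriesSet):
        if n_frames >= data.n_timepoints:
            raise ValueError("cannot drop all timepoints")
        return VoxelTimeSeriesSet(
            parcellation=data.parcellation,
            series=data.series[:, n_frames:].copy(),
            latent_roi_series=None
            if data.latent_roi_series is None
            else data.latent_roi_series[:, n_frames:].copy(),
        )
    arr = np.asarray(data)
    if n_frames >= arr.shape[-1]:
        raise ValueError("cannot drop all timepoints")
    return arr[..., n_frames:].copy()
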