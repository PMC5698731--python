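"""ROI aggregation of voxel series and ROI centroid geometry.

The ROI signal is the unweighted mean of its member voxels' series,
X_I = (1/N_I) sum_{i in I} x_i, and the physical length of a network link is
the Euclidean distance between the two ROI centroids in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.spatial.distance import pdist, squareform

from .synthetic import Parcellation, VoxelTimeSeriesSet

__all__ = ["ROITimeSeriesSet", "LinkGeometry", "roi_timeseries", "link_lengths"]


@dataclass(eq=False)
class ROITimeSeriesSet:
    """One averaged series per ROI; rows ordered by ROI id (1..R)."""

    series: NDArray[np.float64]
    roi_ids: NDArray[np.int64]

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=np.float64)
        self.roi_ids = np.asarray(self.roi_ids, dtype=np.int64)
        if self.series.ndim != 2 or len(self.roi_ids) != self.series.shape[0]:
            raise ValueError("series must be (n_rois, T) aligned with roi_ids")
        if not np.isfinite(self.series).all():
            raise ValueError("ROI series contain non-finite values")

    @property
    def n_rois(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


@dataclass(frozen=True)
class LinkGeometry:
    """Symmetric matrix of pairwise ROI centroid distances in mm."""

    centroid_distance_mm: NDArray[np.float64]

    def __post_init__(self) -> None:
        d = np.asarray(self.centroid_distance_mm, dtype=np.float64)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T) or (np.diag(d) != 0).any() or (d < 0).any():
            raise ValueError("invalid distance matrix")
        object.__setattr__(self, "centroid_distance_mm", d)


def roi_timeseries(
    voxels: VoxelTimeSeriesSet, parcellation: Parcellation | None = None
) -> ROITimeSeriesSet:
    """Average voxel series within each ROI (unweighted mean over members)."""
    parc = parcellation if parcellation is not None else voxels.parcellation
    if parc.n_voxels != voxels.series.shape[0]:
        raise ValueError("parcellation does not cover the voxel series rows")
    sizes = parc.roi_sizes
    empty = np.flatnonzero(sizes == 0)
    if empty.size:
        raise ValueError(f"ROI {empty[0] + 1} has no voxels")
    acc = np.zeros((parc.n_rois, voxels.n_timepoints))
    np.add.at(acc, parc.voxel_labels - 1, voxels.series)
    return ROITimeSeriesSet(
        series=acc / sizes[:, None], roi_ids=np.arange(1, parc.n_rois + 1)
    )


def link_lengths(parcellation: Parcellation) -> LinkGeometry:
    """Pairwise Euclidean distances between ROI centroids, in mm."""
    return LinkGeometry(squareform(pdist(parcellation.centroids_mm)))
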