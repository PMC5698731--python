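"""NIfTI and TSV input/output.

The synthetic path never needs the disk, but real data enters here: a 4-D
BOLD volume plus an integer label atlas (both NIfTI) map onto the same
containers the generator produces.  All tables are tab-separated with a
header row and 1-based ROI ids.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .network import BinaryNetwork
from .parcellate import ROITimeSeriesSet
from .synthetic import Parcellation, VoxelTimeSeriesSet

__all__ = [
    "write_parcellation",
    "read_parcellation",
    "write_voxel_timeseries",
    "read_voxel_timeseries",
    "roi_table",
    "write_roi_timeseries_tsv",
    "read_roi_timeseries_tsv",
    "write_adjacency_tsv",
    "read_adjacency_tsv",
    "write_edge_list_tsv",
    "read_edge_list_tsv",
]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def write_parcellation(parc: Parcellation, nifti_path: str | Path) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int16), _affine(parc.voxel_size_mm))
    nib.save(img, str(nifti_path))


def read_parcellation(
    nifti_path: str | Path,
    homotopic_pairs: tuple[tuple[int, int], ...] = (),
) -> Parcellation:
    img = nib.load(str(nifti_path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Parcellation(
        grid_shape=labels.shape,
        voxel_size_mm=voxel_size,
        labels=labels,
        homotopic_pairs=homotopic_pairs,
    )


def write_voxel_timeseries(vts: VoxelTimeSeriesSet, path: str | Path) -> None:
    parc = vts.parcellation
    grid = np.zeros(parc.grid_shape + (vts.n_timepoints,), dtype=np.float32)
    grid[parc.mask] = vts.series
    nib.save(nib.Nifti1Image(grid, _affine(parc.voxel_size_mm)), str(path))


def read_voxel_timeseries(
    path: str | Path, parcellation: Parcellation
) -> VoxelTimeSeriesSet:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[:3] != parcellation.grid_shape:
        raise ValueError(
            f"volume shape {data.shape} does not match grid {parcellation.grid_shape}"
        )
    return VoxelTimeSeriesSet(
        parcellation=parcellation, series=data[parcellation.mask]
    )


def roi_table(parc: Parcellation) -> pd.DataFrame:
    partner = np.zeros(parc.n_rois, dtype=int)
    for a, b in parc.homotopic_pairs:
        partner[a - 1] = b
        partner[b - 1] = a
    return pd.DataFrame(
        {
            "roi_id": np.arange(1, parc.n_rois + 1),
            "size": parc.roi_sizes,
            "centroid_x_mm": parc.centroids_mm[:, 0],
            "centroid_y_mm": parc.centroids_mm[:, 1],
            "centroid_z_mm": parc.centroids_mm[:, 2],
            "homotopic_partner": partner,
        }
    )


def write_roi_timeseries_tsv(roits: ROITimeSeriesSet, path: str | Path) -> None:
    frame = pd.DataFrame(roits.series)
    frame.insert(0, "roi_id", roits.roi_ids)
    frame.to_csv(path, sep="\t", index=False)


def read_roi_timeseries_tsv(path: str | Path) -> ROITimeSeriesSet:
    frame = pd.read_csv(path, sep="\t")
    return ROITimeSeriesSet(
        series=frame.drop(columns="roi_id").to_numpy(float),
        roi_ids=frame["roi_id"].to_numpy(int),
    )


def write_adjacency_tsv(weights: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(weights, float), delimiter="\t")


def read_adjacency_tsv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


def write_edge_list_tsv(net: BinaryNetwork, path: str | Path) -> None:
    pd.DataFrame(
        {"roi_i": net.edges[:, 0] + 1, "roi_j": net.edges[:, 1] + 1}
    ).to_csv(path, sep="\t", index=False)


def read_edge_list_tsv(path: str | Path, n_nodes: int) -> BinaryNetwork:
    frame = pd.read_csv(path, sep="\t")
    edges = frame[["roi_i", "roi_j"]].to_numpy(int) - 1
    return BinaryNetwork.from_edges(n_nodes, edges)
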