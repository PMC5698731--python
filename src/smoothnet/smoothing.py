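"""Gaussian spatial smoothing of voxel time series, parameterized by FWHM.

Each voxel's series is replaced by a kernel-weighted average of neighboring
voxels' series,

    x_i  <-  sum_j G_i(j) x_j / sum_j G_i(j),

where G is an isotropic Gaussian evaluated in millimetre space and truncated
where its weight is negligible.  The normalization makes a constant field a
fixed point of the operator at any kernel width.

Two boundary policies are offered because volumetric pipelines differ in how
they treat the brain edge: ``mask_renormalized`` restricts both sums to
in-mask voxels (no edge attenuation), ``unmasked`` treats out-of-mask signal
as zero and divides by the full kernel sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.fft import irfftn, next_fast_len, rfftn

from .synthetic import VoxelTimeSeriesSet

__all__ = [
    "FWHM_TO_SIGMA",
    "SmoothingKernel",
    "make_gaussian_kernel",
    "smooth_timeseries",
]

#: sigma = FWHM * FWHM_TO_SIGMA, the standard Gaussian relation
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

_MASK_POLICIES = ("mask_renormalized", "unmasked")


@dataclass(frozen=True)
class SmoothingKernel:
    """Truncated Gaussian kernel sampled at voxel offsets.

    ``weights`` is an odd-shaped 3-D array of unnormalized Gaussian values;
    the center voxel always carries weight 1.  FWHM 0 yields the identity
    kernel (a single unit weight).
    """

    fwhm_mm: float
    sigma_mm: float
    truncation_radius_sigma: float
    voxel_size_mm: tuple[float, float, float]
    weights: NDArray[np.float64]

    @property
    def is_identity(self) -> bool:
        return self.weights.size == 1


def make_gaussian_kernel(
    fwhm_mm: float,
    voxel_size_mm: tuple[float, float, float],
    truncation_radius_sigma: float = 4.0,
) -> SmoothingKernel:
    """Sample a Gaussian of the given FWHM on the voxel grid.

    Weights at mm-offset r are exp(-|r|^2 / (2 sigma^2)); offsets beyond
    ``truncation_radius_sigma * sigma`` along any axis are dropped (the
    truncated weights are < 3.4e-4 of the center at the default 4 sigma).
    Anisotropic voxels are handled by evaluating the Gaussian in mm space.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    voxel_size_mm = tuple(float(v) for v in voxel_size_mm)
    if any(v <= 0 for v in voxel_size_mm):
        raise ValueError("voxel sizes must be positive")
    if truncation_radius_sigma <= 0:
        raise ValueError("truncation_radius_sigma must be positive")
    sigma = fwhm_mm * FWHM_TO_SIGMA
    if fwhm_mm == 0:
        weights = np.ones((1, 1, 1))
    else:
        radii = [
            int(math.floor(truncation_radius_sigma * sigma / v)) for v in voxel_size_mm
        ]
        offsets = [
            np.arange(-r, r + 1) * v for r, v in zip(radii, voxel_size_mm)
        ]
        dx, dy, dz = np.meshgrid(*offsets, indexing="ij")
        r2 = dx**2 + dy**2 + dz**2
        weights = np.exp(-r2 / (2.0 * sigma**2))
    return SmoothingKernel(
        fwhm_mm=float(fwhm_mm),
        sigma_mm=sigma,
        truncation_radius_sigma=float(truncation_radius_sigma),
        voxel_size_mm=voxel_size_mm,
        weights=weights,
    )


def _convolve_same(
    field: NDArray[np.float64], kernel: NDArray[np.float64]
) -> NDArray[np.float64]:
    """'same'-mode convolution over the three leading axes via real FFTs.

    ``field`` may be 3-D or 4-D (trailing time axis); the kernel has odd
    shape, so the 'same' crop is centered exactly on the input grid.
    """
    spatial = field.shape[:3]
    full = [s + k - 1 for s, k in zip(spatial, kernel.shape)]
    fshape = [next_fast_len(n) for n in full]
    kf = rfftn(kernel, s=fshape)
    xf = rfftn(field, s=fshape, axes=(0, 1, 2))
    if field.ndim == 4:
        kf = kf[..., None]
    out = irfftn(kf * xf, s=fshape, axes=(0, 1, 2))
    starts = [(k - 1) // 2 for k in kernel.shape]
    sl = tuple(slice(s, s + n) for s, n in zip(starts, spatial))
    return out[sl]


def smooth_timeseries(
    voxels: VoxelTimeSeriesSet,
    kernel: SmoothingKernel,
    mask_policy: str = "mask_renormalized",
) -> VoxelTimeSeriesSet:
    """Apply the kernel to every timepoint independently.

    Under ``mask_renormalized`` the numerator and denominator sums run over
    in-mask voxels only, so edge voxels are averages of their in-mask
    neighborhood.  Under ``unmasked`` the out-of-mask signal is treated as
    zero and the denominator is the full kernel sum, attenuating edges.
    Grid, mask, and series length are unchanged.
    """
    if mask_policy not in _MASK_POLICIES:
        raise ValueError(f"mask_policy must be one of {_MASK_POLICIES}")
    parc = voxels.parcellation
    if not np.allclose(parc.voxel_size_mm, kernel.voxel_size_mm):
        raise ValueError(
            f"kernel voxel size {kernel.voxel_size_mm} does not match data "
            f"voxel size {parc.voxel_size_mm}"
        )
    if parc.n_voxels == 0:
        raise ValueError("mask is empty")
    if kernel.is_identity:
        return VoxelTimeSeriesSet(parcellation=parc, series=voxels.series.copy())

    mask = parc.mask
    grid = np.zeros(parc.grid_shape + (voxels.n_timepoints,))
    grid[mask] = voxels.series

    num = _convolve_same(grid, kernel.weights)
    if mask_policy == "mask_renormalized":
        denom = _convolve_same(mask.astype(float), kernel.weights)
    else:
        denom = np.full(parc.grid_shape, kernel.weights.sum())
    out = num[mask] / denom[mask][:, None]
    return VoxelTimeSeriesSet(parcellation=parc, series=out)
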