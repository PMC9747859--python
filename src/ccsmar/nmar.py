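"""Normalized sinogram inpainting: the engine of both correction stages.

Metal-corrupted projection bins are treated as missing data. Direct
linear interpolation across the metal trace introduces new streaks near
high-contrast structures, so the original sinogram is first *normalized*
by the sinogram of a clustered prior image: the ratio is close to 1 and
smooth wherever the prior captures the anatomy, and interpolating the
ratio instead of the raw data avoids interpolating across bone edges.
After interpolation, multiplying back by the prior sinogram
(*denormalization*) restores the anatomy inside the trace.

The metal trace itself is the forward projection of the segmented metal
mask, binarized, optionally dilated by a disk in sinogram space (stage 1
only — dilation absorbs uncertainty in the metal threshold, but blurs
tissue adjacent to the metal, so the second stage smooths without
dilating) and Gaussian-smoothed to suppress photon-noise speckle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .imaging_io import CTImage
from .projection import ProjectionGeometry, Sinogram, fbp_reconstruct, forward_project, project_values

__all__ = [
    "MetalTrace",
    "build_metal_trace",
    "normalize_sinogram",
    "interpolate_trace",
    "denormalize_sinogram",
    "nmar_inpaint",
    "nmar_correct",
]

logger = logging.getLogger(__name__)


@dataclass
class MetalTrace:
    """Sinogram-domain footprint of the metal: soft weights and a binary mask."""

    weights: np.ndarray
    binary: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.binary = np.asarray(self.binary, dtype=bool)
        if self.weights.shape != self.binary.shape:
            raise ValueError("weights and binary mask must share a shape")
        if self.weights.min() < 0 or self.weights.max() > 1:
            raise ValueError("trace weights must lie in [0, 1]")
        if (self.binary & (self.weights <= 0)).any():
            raise ValueError("binary trace must be contained in the support of the weights")

    @property
    def is_empty(self) -> bool:
        return not self.binary.any()


def build_metal_trace(
    metal_mask: np.ndarray,
    geometry: ProjectionGeometry,
    dilate: bool = True,
    disk_radius: int = 2,
    sigma: float = 1.0,
    trace_threshold: float = 0.05,
) -> MetalTrace:
    """Project the metal mask and turn it into an inpainting mask.

    An empty metal mask yields an all-false trace, signalling that there
    is nothing to correct.
    """
    metal_mask = np.asarray(metal_mask, dtype=bool)
    if not metal_mask.any():
        shape = (geometry.n_angles, geometry.n_detectors)
        return MetalTrace(np.zeros(shape), np.zeros(shape, dtype=bool))
    sino = project_values(metal_mask.astype(np.float64), geometry)
    hard = sino > 0
    if dilate:
        hard = ndi.binary_dilation(hard, structure=disk(disk_radius))
    weights = ndi.gaussian_filter(hard.astype(np.float64), sigma=sigma)
    peak = weights.max()
    if peak > 0:
        weights = weights / peak
    return MetalTrace(weights, weights > trace_threshold)


def normalize_sinogram(original: Sinogram, clustered: Sinogram, epsilon: float | None = None) -> Sinogram:
    """Pointwise ``original / max(clustered, epsilon)``.

    The guard engages only in bins whose prior projection is (near)
    zero — rays essentially through air. Its default, 1% of the mean
    positive clustered value, is far below every ray that traverses
    tissue, yet large enough to keep the ratio O(1) in air bins: those
    bins anchor the linear interpolation across the metal trace, and a
    vanishing divisor there would propagate huge ratios into the trace
    and destroy the reconstruction after denormalization.
    """
    if not original.same_geometry(clustered):
        raise ValueError("original and clustered sinograms must share a geometry")
    if epsilon is None:
        positive = clustered.values[clustered.values > 0]
        epsilon = 1e-2 * (positive.mean() if positive.size else 1.0)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return Sinogram(original.values / np.maximum(clustered.values, epsilon), original.geometry)


def interpolate_trace(normalized: Sinogram, trace: MetalTrace) -> Sinogram:
    """Replace flagged bins by per-angle 1-D linear interpolation.

    Within each view (sinogram row), every run of flagged bins is bridged
    linearly between the nearest unflagged bins; runs touching a row edge
    extend the nearest unflagged value. Unflagged bins are returned
    bit-identical. A fully flagged row is filled with its pre-flagging
    mean (and logged), since no anchors exist.
    """
    if trace.binary.shape != normalized.shape:
        raise ValueError("trace shape must match the sinogram")
    out = normalized.values.copy()
    flagged_rows = np.flatnonzero(trace.binary.any(axis=1))
    n_bins = normalized.shape[1]
    bins = np.arange(n_bins)
    for r in flagged_rows:
        flags = trace.binary[r]
        keep = ~flags
        if not keep.any():
            logger.warning("sinogram row %d fully flagged by the metal trace; filling with the row mean", r)
            out[r] = normalized.values[r].mean()
            continue
        out[r, flags] = np.interp(bins[flags], bins[keep], normalized.values[r, keep])
    return Sinogram(out, normalized.geometry)


def denormalize_sinogram(interpolated: Sinogram, clustered: Sinogram) -> Sinogram:
    """Pointwise product, undoing the normalization outside clipped bins."""
    if not interpolated.same_geometry(clustered):
        raise ValueError("interpolated and clustered sinograms must share a geometry")
    return Sinogram(interpolated.values * clustered.values, interpolated.geometry)


def nmar_inpaint(original: Sinogram, clustered: Sinogram, trace: MetalTrace, epsilon: float | None = None) -> Sinogram:
    """Normalize → interpolate → denormalize, touching only flagged bins.

    Bins outside the binary trace are copied from the original sinogram
    bit-for-bit; the normalized/denormalized values only ever land inside
    the trace.
    """
    if trace.is_empty:
        return original.copy()
    normalized = normalize_sinogram(original, clustered, epsilon)
    inpainted = interpolate_trace(normalized, trace)
    denorm = denormalize_sinogram(inpainted, clustered)
    corrected = original.values.copy()
    corrected[trace.binary] = denorm.values[trace.binary]
    return Sinogram(corrected, original.geometry)


def nmar_correct(
    original_image: CTImage,
    clustered: CTImage | Sinogram,
    metal_mask: np.ndarray,
    geometry: ProjectionGeometry,
    *,
    dilate: bool = True,
    disk_radius: int = 2,
    sigma: float = 1.0,
    trace_threshold: float = 0.05,
    epsilon: float | None = None,
    filter_name: str = "ramp",
    return_sinograms: bool = False,
):
    """One full normalized-inpainting correction pass.

    Forward-projects the image and the clustered prior (``clustered``
    may also be a precomputed prior sinogram), builds the metal trace,
    inpaints, and reconstructs by filtered back projection. With
    ``return_sinograms`` the corrected and original sinograms are
    returned alongside the image for inspection.
    """
    if original_image.shape != metal_mask.shape:
        raise ValueError("metal mask must match the image shape")
    original_sino = forward_project(original_image, geometry)
    if isinstance(clustered, Sinogram):
        clustered_sino = clustered
    else:
        if clustered.shape != original_image.shape:
            raise ValueError("clustered image must match the original image shape")
        clustered_sino = forward_project(clustered, geometry)
    trace = build_metal_trace(metal_mask, geometry, dilate, disk_radius, sigma, trace_threshold)
    corrected_sino = nmar_inpaint(original_sino, clustered_sino, trace, epsilon)
    corrected = fbp_reconstruct(corrected_sino, filter_name, original_image.shape, spacing=original_image.spacing)
    if return_sinograms:
        return corrected, corrected_sino, original_sino, trace
    return corrected
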