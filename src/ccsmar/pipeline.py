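"""The two-stage CCS-MAR correction pipeline.

Stage 1 (classic normalized inpainting): segment metal (≥ ``metal_hu``)
and air (≤ ``air_hu``), k-means-cluster the remaining tissue into k = 3
classes, stamp the air back in, and run
normalize → interpolate → denormalize over the *dilated* and smoothed
metal trace, reconstructing the first corrected scan by filtered back
projection.

Stage 1 typically leaves intense dark streaks near the metal, because
those streaks are clustered as lung in the prior. Stage 2 repairs the
prior rather than the image: pixels where the first correction moved the
image by more than ``diff_hu`` (default 200 HU) are reset to 0 HU on the
first corrected scan, the result is re-clustered with a single 3×3
spatial-relationship majority pass, and the two clusterings are merged
into the *combined clustered scan* (``initial + |spatial − initial|``).
The normalized inpainting then runs again on the original sinogram with
this combined prior and an *undilated* (smoothed-only) metal trace.

The final scan averages the two corrections, adds back the high-pass
noise texture of the original scan, and restores the original pixels
inside the metal mask.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy import ndimage as ndi

from . import clustering as cl
from .imaging_io import AIR_HU, CTImage, pad_to_square
from .nmar import build_metal_trace, nmar_inpaint
from .projection import ProjectionGeometry, Sinogram, fbp_reconstruct, forward_project

__all__ = ["MARConfig", "stage1_correct", "diff_mask", "stage2_correct", "assemble_final", "run_ccs_mar"]

logger = logging.getLogger(__name__)


@dataclass
class MARConfig:
    """Every tunable of the correction pipeline, with defaults.

    ``metal_hu`` (2000, valid 2000–2500) and ``air_hu`` (−950) drive the
    threshold segmentations; ``diff_hu`` (200, valid 150–200) flags
    residual streaks between the stages and ``replace_hu`` (0) is the
    value they are reset to; ``k`` (3) and ``mask_size`` (3) control the
    tissue clustering; ``disk_radius`` / ``sigma`` / ``trace_threshold``
    / ``epsilon`` are the inpainting-trace knobs; ``highpass_sigma``
    (1.5 px) shapes the noise-texture term; ``combine_rule`` selects how
    the two stage-2 clusterings merge.
    """

    metal_hu: float = 2000.0
    air_hu: float = -950.0
    diff_hu: float = 200.0
    replace_hu: float = 0.0
    k: int = 3
    mask_size: int = 3
    n_angles: int | None = None
    filter_name: str = "ramp"
    disk_radius: int = 2
    sigma: float = 1.0
    trace_threshold: float = 0.05
    epsilon: float | None = None
    highpass_sigma: float = 1.5
    combine_rule: str = "add-absdiff"
    reinsert_metal: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2000.0 <= self.metal_hu <= 2500.0:
            raise ValueError("metal_hu must lie in [2000, 2500]")
        if not 150.0 <= self.diff_hu <= 200.0:
            raise ValueError("diff_hu must lie in [150, 200]")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.mask_size < 3 or self.mask_size % 2 == 0:
            raise ValueError("mask_size must be odd and >= 3")
        if self.combine_rule not in ("add-absdiff", "replace-where-different"):
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")

    def geometry_for(self, shape: tuple[int, int]) -> ProjectionGeometry:
        return ProjectionGeometry.for_image(shape, self.n_angles)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "MARConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown MARConfig keys: {sorted(unknown)}")
        return cls(**data)


def _clustered_prior(image: CTImage, metal: np.ndarray, air: np.ndarray, cfg: MARConfig, spatial: bool) -> tuple[CTImage, cl.LabelMap]:
    """Cluster tissue, optionally run the majority pass, stamp air, paint priors."""
    labels = cl.kmeans_cluster(image, exclude=metal | air, k=cfg.k, seed=cfg.seed)
    priors = cl.ClusterPriors.from_image(image, labels)
    labels.labels[air] = cl.AIR_LABEL
    if spatial:
        labels = cl.apply_spatial_relationships(labels, cl.NeighborhoodSpec(cfg.mask_size))
        labels.labels[air] = cl.AIR_LABEL
    return cl.build_clustered_image(labels, priors, image.spacing), labels


def stage1_correct(ct_art: CTImage, cfg: MARConfig = MARConfig()) -> tuple[CTImage, CTImage, np.ndarray, np.ndarray]:
    """First correction: dilated-trace normalized inpainting.

    Returns ``(first_corrected, initial_clustered, metal_mask, air_mask)``;
    stage 2 consumes all four.
    """
    metal = cl.segment_threshold(ct_art, cfg.metal_hu, "ge")
    air = cl.segment_threshold(ct_art, cfg.air_hu, "le")
    initial_clustered, _ = _clustered_prior(ct_art, metal, air, cfg, spatial=False)
    geometry = cfg.geometry_for(ct_art.shape)
    original_sino = forward_project(ct_art, geometry)
    clustered_sino = forward_project(initial_clustered, geometry)
    trace = build_metal_trace(metal, geometry, True, cfg.disk_radius, cfg.sigma, cfg.trace_threshold)
    corrected_sino = nmar_inpaint(original_sino, clustered_sino, trace, cfg.epsilon)
    first = fbp_reconstruct(corrected_sino, cfg.filter_name, ct_art.shape, spacing=ct_art.spacing)
    return first, initial_clustered, metal, air


def diff_mask(ct_art: CTImage, first_corrected: CTImage, diff_hu: float = 200.0) -> np.ndarray:
    """Pixels the first correction moved by more than ``diff_hu``."""
    if ct_art.shape != first_corrected.shape:
        raise ValueError(f"shape mismatch: {ct_art.shape} vs {first_corrected.shape}")
    return np.abs(ct_art.pixels - first_corrected.pixels) > diff_hu


def stage2_correct(
    ct_art: CTImage,
    first_corrected: CTImage,
    diffmask: np.ndarray,
    initial_clustered: CTImage,
    air_mask: np.ndarray,
    metal_mask: np.ndarray,
    cfg: MARConfig = MARConfig(),
) -> CTImage:
    """Second correction: combined clustered prior, undilated trace."""
    replaced = first_corrected.copy()
    replaced.pixels[diffmask] = cfg.replace_hu
    spatial_clustered, _ = _clustered_prior(replaced, metal_mask, air_mask, cfg, spatial=True)
    combined = cl.combine_clustered(initial_clustered, spatial_clustered, cfg.combine_rule)
    geometry = cfg.geometry_for(ct_art.shape)
    original_sino = forward_project(ct_art, geometry)
    combined_sino = forward_project(combined, geometry)
    trace = build_metal_trace(metal_mask, geometry, False, cfg.disk_radius, cfg.sigma, cfg.trace_threshold)
    corrected_sino = nmar_inpaint(original_sino, combined_sino, trace, cfg.epsilon)
    return fbp_reconstruct(corrected_sino, cfg.filter_name, ct_art.shape, spacing=ct_art.spacing)


def high_pass(image: CTImage, sigma: float) -> np.ndarray:
    """Unsharp-mask high-pass: ``x − gaussian(x, sigma)``."""
    return image.pixels - ndi.gaussian_filter(image.pixels, sigma)


def assemble_final(
    first_corrected: CTImage,
    second_corrected: CTImage,
    ct_art: CTImage,
    metal_mask: np.ndarray,
    cfg: MARConfig = MARConfig(),
) -> CTImage:
    """Average the two corrections, add noise texture, restore metal pixels.

    The high-pass texture term is zeroed inside the metal mask so metal
    bloom is not re-added; the metal pixels themselves are copied back
    from the original scan afterwards (configurable via
    ``reinsert_metal``).
    """
    if not (first_corrected.shape == second_corrected.shape == ct_art.shape == metal_mask.shape):
        raise ValueError("all inputs must share a shape")
    corrected = (first_corrected.pixels + second_corrected.pixels) / 2.0
    texture = high_pass(ct_art, cfg.highpass_sigma)
    texture[metal_mask] = 0.0
    out = corrected + texture
    if cfg.reinsert_metal:
        out[metal_mask] = ct_art.pixels[metal_mask]
    return ct_art.with_pixels(out)


def run_ccs_mar(ct_art: CTImage, cfg: MARConfig = MARConfig()) -> tuple[CTImage, dict[str, Any]]:
    """Full two-stage correction; deterministic for fixed inputs.

    Returns the corrected scan together with a provenance record holding
    every intermediate image, the masks, the config echo and per-stage
    timings. Non-square inputs are air-padded to square for projection
    and cropped back at the end.
    """
    crop = None
    original = ct_art
    if not ct_art.is_square:
        ct_art, crop = pad_to_square(ct_art)
    provenance: dict[str, Any] = {"config": cfg.to_dict(), "timings_s": {}}

    def _timed(stage: str, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:
            raise RuntimeError(f"CCS-MAR {stage} failed: {exc}") from exc
        provenance["timings_s"][stage] = time.perf_counter() - t0
        return result

    first, initial_clustered, metal, air = _timed("stage1", stage1_correct, ct_art, cfg)
    logger.info("stage1: %d metal px, %d air px (%.2fs)", metal.sum(), air.sum(), provenance["timings_s"]["stage1"])
    dm = diff_mask(ct_art, first, cfg.diff_hu)
    second = _timed("stage2", stage2_correct, ct_art, first, dm, initial_clustered, air, metal, cfg)
    logger.info("stage2: %d flagged px (%.2fs)", dm.sum(), provenance["timings_s"]["stage2"])
    ct_cor = _timed("assemble", assemble_final, first, second, ct_art, metal, cfg)
    provenance.update(
        first_corrected=first,
        second_corrected=second,
        initial_clustered=initial_clustered,
        metal_mask=metal,
        air_mask=air,
        diff_mask=dm,
        metal_pixels=int(metal.sum()),
        flagged_pixels=int(dm.sum()),
    )
    if crop is not None:
        ct_cor = original.with_pixels(ct_cor.pixels[crop])
    return ct_cor, provenance
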