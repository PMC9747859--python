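"""Parallel-beam forward projection (Radon transform) and filtered back
projection, the bridge between the image and sinogram domains.

All sinograms used by one correction run must share a single
:class:`ProjectionGeometry` so that the original, metal and clustered
sinograms are bin-aligned — the normalized-inpainting division is
meaningless otherwise.

Two projection domains are supported:

``hu-offset`` (default)
    Projects ``HU + 1000``, i.e. an affine surrogate for attenuation in
    which air is exactly zero. The normalized-inpainting core only ever
    forms *ratios* of sinograms that share a domain, so any positive
    affine rescaling of attenuation is admissible and this choice avoids
    committing to a water attenuation coefficient.
``attenuation``
    Converts HU to linear attenuation (mm⁻¹) via :func:`hu_to_mu` and
    scales line integrals by the pixel pitch, giving dimensionless
    physical path integrals. Used by the artifact simulator, which needs
    real units for Beer–Lambert photon statistics.

Geometry convention (inherited from ``skimage.transform.radon``): for an
``n``×``n`` image, a pixel at (row, col) projects, at angle θ (degrees),
to detector bin ``n//2 + (col − n//2)·cosθ − (row − n//2)·sinθ``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon, radon

from .imaging_io import CTImage

__all__ = [
    "ProjectionGeometry",
    "Sinogram",
    "hu_to_mu",
    "mu_to_hu",
    "project_values",
    "forward_project",
    "fbp_reconstruct",
    "HU_OFFSET",
]

HU_OFFSET = 1000.0
FBP_FILTERS = ("ramp", "hann", "hamming", "cosine", "shepp-logan")


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam acquisition geometry shared by every sinogram of a run.

    Parameters
    ----------
    n_angles : int
        Number of view angles, uniformly spaced over [0, 180).
    n_detectors : int
        Detector bin count; with ``circle_mask`` this equals the image
        width, otherwise it must cover the image diagonal.
    circle_mask : bool
        Restrict support to the inscribed circle (the usual CT field of
        view). Pixels outside the circle are treated as air.
    """

    n_angles: int
    n_detectors: int
    circle_mask: bool = True

    def __post_init__(self) -> None:
        if self.n_angles < 2:
            raise ValueError("need at least 2 view angles")
        if self.n_detectors < 2:
            raise ValueError("need at least 2 detector bins")

    @property
    def angles(self) -> np.ndarray:
        """View angles in degrees, uniform over [0, 180)."""
        return np.arange(self.n_angles) * (180.0 / self.n_angles)

    @classmethod
    def for_image(cls, shape: tuple[int, int], n_angles: int | None = None) -> "ProjectionGeometry":
        """Nyquist-adequate default geometry for a square image."""
        n = shape[0]
        if shape[0] != shape[1]:
            raise ValueError(f"square image required, got {shape}")
        return cls(n_angles=n_angles if n_angles is not None else max(180, n), n_detectors=n)

    def validate_image(self, shape: tuple[int, int]) -> None:
        if shape[0] != shape[1]:
            raise ValueError(f"forward projection requires a square image, got {shape}")
        if self.circle_mask:
            if self.n_detectors < shape[1]:
                raise ValueError("n_detectors must be >= image width when circle_mask is set")
        else:
            diag = int(np.ceil(np.hypot(*shape)))
            if self.n_detectors < diag:
                raise ValueError("n_detectors must cover the image diagonal when circle_mask is off")


@dataclass
class Sinogram:
    """Projection data indexed ``(angle index, detector bin)``."""

    values: np.ndarray
    geometry: ProjectionGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_angles, self.geometry.n_detectors)
        if self.values.shape != expected:
            raise ValueError(f"sinogram shape {self.values.shape} != geometry {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.geometry)

    def same_geometry(self, other: "Sinogram") -> bool:
        return self.geometry == other.geometry


def hu_to_mu(image: CTImage, mu_water: float = 0.02) -> np.ndarray:
    """Linear attenuation (mm⁻¹) from HU: ``mu_water · (1 + HU/1000)``, clipped at 0."""
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    return np.clip(mu_water * (1.0 + image.pixels / 1000.0), 0.0, None)


def mu_to_hu(mu: np.ndarray, mu_water: float = 0.02, spacing: tuple[float, float] = (1.0, 1.0)) -> CTImage:
    """Inverse of :func:`hu_to_mu` on non-clipped values."""
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    return CTImage((np.asarray(mu, dtype=np.float64) / mu_water - 1.0) * 1000.0, spacing)


def _circle_mask(n: int) -> np.ndarray:
    r = n // 2
    yy, xx = np.ogrid[:n, :n]
    return (yy - r) ** 2 + (xx - r) ** 2 <= r**2


def project_values(values: np.ndarray, geometry: ProjectionGeometry) -> np.ndarray:
    """Raw Radon transform of a plain array (no unit handling).

    Values outside the inscribed circle are zeroed first when the
    geometry carries a circular field of view. Returns an
    ``(n_angles, n_detectors)`` array of pixel-unit line integrals.
    """
    values = np.asarray(values, dtype=np.float64)
    geometry.validate_image(values.shape)
    if geometry.circle_mask:
        values = np.where(_circle_mask(values.shape[0]), values, 0.0)
    sino = radon(values, theta=geometry.angles, circle=geometry.circle_mask)
    return np.ascontiguousarray(sino.T)  # skimage returns (detector, angle)


def forward_project(image: CTImage, geometry: ProjectionGeometry, domain: str = "hu-offset", *, mu_water: float = 0.02) -> Sinogram:
    """Forward-project a CT slice into a sinogram.

    ``domain`` selects the projected quantity (see module docstring);
    line integrals in the attenuation domain are scaled by the column
    pixel pitch so they are dimensionless.
    """
    if domain == "hu-offset":
        vals = image.pixels + HU_OFFSET
    elif domain == "attenuation":
        vals = hu_to_mu(image, mu_water) * image.spacing[1]
    else:
        raise ValueError(f"unknown projection domain {domain!r}")
    return Sinogram(project_values(vals, geometry), geometry)


def fbp_reconstruct(
    sinogram: Sinogram,
    filter_name: str = "hann",
    output_shape: tuple[int, int] | None = None,
    *,
    domain: str = "hu-offset",
    spacing: tuple[float, float] = (1.0, 1.0),
    mu_water: float = 0.02,
) -> CTImage:
    """Filtered back projection of a sinogram back to a CT slice.

    The inverse of the domain handling in :func:`forward_project` is
    applied, so round-tripping an image through
    ``forward_project``/``fbp_reconstruct`` approximates identity.
    """
    if filter_name not in FBP_FILTERS:
        raise ValueError(f"unknown FBP filter {filter_name!r}; expected one of {FBP_FILTERS}")
    geom = sinogram.geometry
    n = output_shape[0] if output_shape is not None else geom.n_detectors
    if output_shape is not None and output_shape[0] != output_shape[1]:
        raise ValueError("FBP output must be square")
    recon = iradon(
        sinogram.values.T,
        theta=geom.angles,
        filter_name=filter_name,
        circle=geom.circle_mask,
        output_size=n,
    )
    if domain == "hu-offset":
        return CTImage(recon - HU_OFFSET, spacing)
    if domain == "attenuation":
        return mu_to_hu(recon / spacing[1], mu_water, spacing)
    raise ValueError(f"unknown projection domain {domain!r}")
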