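"""Synthetic thorax phantom and transducer-artifact simulator.

Real evaluation of a metal artifact reduction algorithm needs paired
scans of the same anatomy with and without the metal in place. This
module builds such pairs entirely in software:

* :func:`generate_phantom` renders a piecewise-constant 2-D thorax
  slice — body, two lungs, heart, spine, ribs — plus a high-attenuation
  metal bar near the anterior surface standing in for the metal stack of
  an ultrasound transducer. That image is the artifact-free reference.
* :func:`simulate_artifact_scan` produces the corrupted scan by running
  the reference through a minimal polychromatic acquisition model: a
  two-bin X-ray spectrum whose bins attenuate metal very differently
  (beam hardening) and Poisson photon statistics at finite tube output
  (photon starvation), followed by log transform and filtered back
  projection. Dark and bright streaks radiate from the metal exactly as
  in scanner data, and severity grows with the metal width.

The model deliberately omits scatter, detector crosstalk and fan-beam
effects; it exists to exercise the correction pipeline, not to replicate
any particular scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .imaging_io import AIR_HU, CTImage
from .projection import ProjectionGeometry, Sinogram, fbp_reconstruct, hu_to_mu, project_values

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "AcquisitionSpec",
    "generate_phantom",
    "simulate_artifact_scan",
    "make_fixture_pair",
    "FIXTURE_SPECS",
    "named_fixture",
]


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: centre (row, col) and semi-axes in pixels."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    hu: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        a, b = self.semi_axes
        return ((rr - self.center[0]) / a) ** 2 + ((cc - self.center[1]) / b) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue HU values of the synthetic thorax slice.

    The default 256×256 grid at 1.5 mm pitch gives a 38.4 cm field of
    view. Tissue HU follow standard values: soft tissue 40, lung −800,
    bone 700, air −1000; the metal insert is 3000 HU, comfortably above
    the 2000–2500 HU segmentation band. ``metal_width_mm`` mirrors the
    2–6 cm span of clinical cardiac transducers.
    """

    shape: tuple[int, int] = (256, 256)
    spacing: tuple[float, float] = (1.5, 1.5)
    soft_hu: float = 40.0
    lung_hu: float = -800.0
    heart_hu: float = 50.0
    bone_hu: float = 700.0
    metal_hu: float = 3000.0
    metal_width_mm: float = 40.0
    metal_thickness_mm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metal_hu and self.metal_hu < 3000:
            raise ValueError("metal insert must be >= 3000 HU")
        if self.metal_width_mm < 0:
            raise ValueError("metal width must be non-negative")


def _structures(spec: PhantomSpec) -> list[Ellipse]:
    n = spec.shape[0]
    c = n / 2
    s = n / 256.0  # scale all default pixel dimensions with the grid
    body = Ellipse((c + 8 * s, c), (88 * s, 112 * s), spec.soft_hu)
    lung_l = Ellipse((c + 8 * s, c - 52 * s), (58 * s, 38 * s), spec.lung_hu)
    lung_r = Ellipse((c + 8 * s, c + 52 * s), (58 * s, 38 * s), spec.lung_hu)
    heart = Ellipse((c + 18 * s, c - 8 * s), (34 * s, 26 * s), spec.heart_hu)
    spine = Ellipse((c + 78 * s, c), (14 * s, 12 * s), spec.bone_hu)
    ribs = [
        Ellipse((c - 60 * s, c - 70 * s), (6 * s, 10 * s), spec.bone_hu),
        Ellipse((c - 60 * s, c + 70 * s), (6 * s, 10 * s), spec.bone_hu),
        Ellipse((c + 40 * s, c - 95 * s), (10 * s, 5 * s), spec.bone_hu),
        Ellipse((c + 40 * s, c + 95 * s), (10 * s, 5 * s), spec.bone_hu),
    ]
    return [body, lung_l, lung_r, heart, spine, *ribs]


def _metal_mask(spec: PhantomSpec) -> np.ndarray:
    mask = np.zeros(spec.shape, dtype=bool)
    if spec.metal_width_mm <= 0:
        return mask
    n = spec.shape[0]
    s = n / 256.0  # mm dimensions refer to the default grid; anatomy scales with it
    half_w = max(1, round(spec.metal_width_mm / spec.spacing[1] / 2 * s))
    thick = max(2, round(spec.metal_thickness_mm / spec.spacing[0] * s))
    top = round((128 - 74) * s)  # just inside the anterior body surface
    c = n // 2
    mask[top : top + thick, c - half_w : c + half_w] = True
    return mask


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> CTImage:
    """Render the artifact-free reference slice (deterministic per spec)."""
    img = np.full(spec.shape, AIR_HU, dtype=np.float64)
    structures = _structures(spec)
    for e in structures:
        img[e.mask(spec.shape)] = e.hu
    metal = _metal_mask(spec)
    lungs = structures[1].mask(spec.shape) | structures[2].mask(spec.shape)
    if (metal & lungs).any():
        raise ValueError("metal insert overlaps lung; adjust the phantom spec")
    img[metal] = spec.metal_hu
    return CTImage(img, spec.spacing)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Minimal polychromatic acquisition model.

    Two spectral bins (weights 0.6/0.4) attenuate soft tissue almost
    equally (ratio 1.2) but metal very unequally (ratio 3), the smallest
    model that produces beam-hardening shading plus streaks. ``i0`` is
    the unattenuated photon count per ray; 10⁵ leaves visible
    photon-starvation streaks behind centimetres of metal while body
    rays stay at usable statistics. ``mu_water`` is the water
    attenuation coefficient (mm⁻¹) used for the HU↔μ conversion.
    """

    weights: tuple[float, ...] = (0.6, 0.4)
    tissue_scales: tuple[float, ...] = (12.0 / 11.2, 10.0 / 11.2)  # ratio 1.2, weighted mean 1
    metal_scales: tuple[float, ...] = (3.0, 1.0)  # ratio 3
    i0: float = 1e5
    mu_water: float = 0.02
    geometry: ProjectionGeometry | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.tissue_scales) or len(self.weights) != len(self.metal_scales):
            raise ValueError("weights, tissue_scales and metal_scales must have equal length")
        if any(w <= 0 for w in self.weights):
            raise ValueError("spectrum weights must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("spectrum weights must sum to 1")
        if self.i0 <= 0:
            raise ValueError("incident photon count i0 must be positive")


def simulate_artifact_scan(
    ct_ref: CTImage,
    acq: AcquisitionSpec = AcquisitionSpec(),
    metal_mask: np.ndarray | None = None,
    *,
    noise: bool = True,
    filter_name: str = "hann",
) -> CTImage:
    """Corrupt a reference slice with metal artifacts.

    Per spectral bin the attenuation map is scaled (metal much more
    strongly in the low-energy bin), forward projected, attenuated by
    Beer–Lambert, weighted and summed over bins; Poisson noise is added
    (seeded from ``acq.seed``), counts are floored at one photon, and the
    log-transformed sinogram is reconstructed by filtered back
    projection. The weighted tissue scales average to 1, so soft-tissue
    HU stays calibrated while rays through metal are inconsistent across
    bins — the origin of the streaks and shading.
    """
    geometry = acq.geometry or ProjectionGeometry.for_image(ct_ref.shape, n_angles=ct_ref.shape[0])
    if metal_mask is None:
        metal_mask = ct_ref.pixels >= 2500.0
    mu = hu_to_mu(ct_ref, acq.mu_water)
    intensity = np.zeros((geometry.n_angles, geometry.n_detectors))
    for w, ts, ms in zip(acq.weights, acq.tissue_scales, acq.metal_scales):
        mu_bin = np.where(metal_mask, mu * ms, mu * ts)
        proj = project_values(mu_bin * ct_ref.spacing[1], geometry)
        intensity += acq.i0 * w * np.exp(-proj)
    if noise:
        rng = np.random.default_rng(acq.seed)
        intensity = rng.poisson(intensity).astype(np.float64)
    intensity = np.maximum(intensity, 1.0)
    sino = Sinogram(-np.log(intensity / acq.i0), geometry)
    return fbp_reconstruct(
        sino, filter_name, ct_ref.shape, domain="attenuation", spacing=ct_ref.spacing, mu_water=acq.mu_water
    )


def make_fixture_pair(
    phantom: PhantomSpec = PhantomSpec(), acq: AcquisitionSpec = AcquisitionSpec()
) -> tuple[CTImage, CTImage, dict[str, np.ndarray]]:
    """Reference scan, corrupted scan and ground-truth masks in one call."""
    ct_ref = generate_phantom(phantom)
    truth_metal = _metal_mask(phantom)
    ct_art = simulate_artifact_scan(ct_ref, acq, truth_metal)
    structures = _structures(phantom)
    masks = {
        "metal": truth_metal,
        "body": structures[0].mask(phantom.shape),
        "lung": structures[1].mask(phantom.shape) | structures[2].mask(phantom.shape),
        "heart": structures[3].mask(phantom.shape),
        "bone": structures[4].mask(phantom.shape),
    }
    return ct_ref, ct_art, masks


#: The three bundled fixtures mirror the span of transducer metal widths
#: (2 / 4 / 6 cm) that drives artifact severity.
FIXTURE_SPECS: dict[str, PhantomSpec] = {
    "narrow": PhantomSpec(metal_width_mm=20.0, seed=11),
    "medium": PhantomSpec(metal_width_mm=40.0, seed=12),
    "wide": PhantomSpec(metal_width_mm=60.0, seed=13),
}


def named_fixture(name: str, seed: int | None = None) -> tuple[CTImage, CTImage, dict[str, np.ndarray]]:
    """One of the bundled narrow/medium/wide fixtures, optionally reseeded."""
    if name not in FIXTURE_SPECS:
        raise KeyError(f"unknown fixture {name!r}; expected one of {sorted(FIXTURE_SPECS)}")
    spec = FIXTURE_SPECS[name]
    if seed is not None:
        spec = replace(spec, seed=seed)
    return make_fixture_pair(spec, AcquisitionSpec(seed=spec.seed))
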