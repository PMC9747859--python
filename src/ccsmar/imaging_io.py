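"""Reading and writing 2-D CT slices in Hounsfield units.

Every pipeline stage operates on :class:`CTImage`: a float64 grid of HU
values plus the physical pixel spacing. Three on-disk dialects are
supported:

``dicom``
    Single-frame CT slices via :mod:`pydicom`. ``RescaleSlope`` /
    ``RescaleIntercept`` are applied on read; on write, pixels are rounded
    to the nearest integer HU and stored as signed 16-bit with slope 1 /
    intercept 0, so the dialect is lossless only for integer-valued HU.
``nifti``
    NIfTI-1 via :mod:`nibabel`, stored float64 — bit-exact round trips.
    Multi-slice volumes are addressed with ``slice_index``.
``raw-array``
    A NumPy ``.npz`` container with arrays ``pixels`` (float64 HU) and
    ``spacing`` (row_mm, col_mm). Bit-exact; intended for fixtures and
    debugging.

Conventions: row-major arrays, origin at the top-left corner, 0-based
indices. Non-square slices are padded to square with air (−1000 HU)
before forward projection and cropped back afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

AIR_HU = -1000.0

__all__ = ["CTImage", "read_ct_slice", "write_ct_slice", "pad_to_square", "AIR_HU"]


@dataclass
class CTImage:
    """A 2-D axial CT slice in Hounsfield units.

    Parameters
    ----------
    pixels : ndarray
        2-D float array of HU values; must be finite.
    spacing : tuple of float
        Physical pixel size ``(row_mm, col_mm)``, strictly positive.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"CTImage requires a 2-D grid, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("CTImage pixels must all be finite")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"pixel spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def is_square(self) -> bool:
        return self.shape[0] == self.shape[1]

    def copy(self) -> "CTImage":
        return CTImage(self.pixels.copy(), self.spacing)

    def with_pixels(self, pixels: np.ndarray) -> "CTImage":
        """A new image sharing this image's spacing."""
        return CTImage(np.asarray(pixels, dtype=np.float64), self.spacing)


def pad_to_square(image: CTImage, fill: float = AIR_HU) -> tuple[CTImage, tuple[slice, slice]]:
    """Pad a non-square slice with air so projection code sees square support.

    Returns the padded image together with the slices that recover the
    original region (``padded.pixels[rows, cols]`` equals the input).
    """
    r, c = image.shape
    n = max(r, c)
    if r == c:
        return image, (slice(0, r), slice(0, c))
    out = np.full((n, n), fill, dtype=np.float64)
    r0 = (n - r) // 2
    c0 = (n - c) // 2
    out[r0 : r0 + r, c0 : c0 + c] = image.pixels
    return CTImage(out, image.spacing), (slice(r0, r0 + r), slice(c0, c0 + c))


def _require_dialect(dialect: str) -> str:
    known = {"dicom", "nifti", "raw-array"}
    if dialect not in known:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(known)}")
    return dialect


def read_ct_slice(
    path: str | Path,
    dialect: str = "raw-array",
    *,
    slice_index: int = 0,
    default_spacing: tuple[float, float] = (1.0, 1.0),
    slope: float | None = None,
    intercept: float | None = None,
) -> CTImage:
    """Read one axial slice and convert pixel values to HU.

    ``slope``/``intercept`` override (or supply, when the file lacks them)
    the DICOM rescale tags; they are ignored for the other dialects.
    """
    _require_dialect(dialect)
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read CT slice: no such file {path}")
    if dialect == "raw-array":
        with np.load(path) as data:
            pixels = np.asarray(data["pixels"], dtype=np.float64)
            spacing = tuple(np.asarray(data["spacing"], dtype=np.float64)) if "spacing" in data else default_spacing
        return CTImage(pixels, spacing)  # type: ignore[arg-type]
    if dialect == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[:, :, slice_index]
        elif arr.ndim != 2:
            raise IOError(f"cannot interpret NIfTI of shape {arr.shape} as a slice stack: {path}")
        zooms = img.header.get_zooms()[:2]
        spacing = (float(zooms[0]) or default_spacing[0], float(zooms[1]) or default_spacing[1])
        return CTImage(arr, spacing)
    # dicom
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
        raw = ds.pixel_array.astype(np.float64)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure with the path
        raise IOError(f"cannot parse DICOM file {path}: {exc}") from exc
    s = slope if slope is not None else getattr(ds, "RescaleSlope", None)
    b = intercept if intercept is not None else getattr(ds, "RescaleIntercept", None)
    if s is None or b is None:
        raise IOError(
            f"DICOM file {path} lacks RescaleSlope/RescaleIntercept; "
            "pass explicit slope= and intercept= to convert stored values to HU"
        )
    hu = raw * float(s) + float(b)
    ps = getattr(ds, "PixelSpacing", None)
    spacing = (float(ps[0]), float(ps[1])) if ps is not None else default_spacing
    return CTImage(hu, spacing)


def write_ct_slice(image: CTImage, path: str | Path, dialect: str = "raw-array") -> None:
    """Write a slice so that :func:`read_ct_slice` recovers it.

    The ``nifti`` and ``raw-array`` dialects are bit-exact; ``dicom``
    rounds to integer HU (see module docstring).
    """
    _require_dialect(dialect)
    path = Path(path)
    if path.is_dir():
        raise IOError(f"cannot write CT slice: {path} is a directory")
    if dialect == "raw-array":
        np.savez(path, pixels=image.pixels, spacing=np.asarray(image.spacing, dtype=np.float64))
        return
    if dialect == "nifti":
        import nibabel as nib

        affine = np.diag([image.spacing[0], image.spacing[1], 1.0, 1.0])
        nii = nib.Nifti1Image(image.pixels.astype(np.float64), affine)
        nii.header.set_zooms((image.spacing[0], image.spacing[1]))
        nib.save(nii, str(path))
        return
    _write_dicom(image, path)


def _write_dicom(image: CTImage, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    hu = np.rint(image.pixels)
    if hu.min() < -32768 or hu.max() > 32767:
        raise IOError("HU values out of int16 range; DICOM dialect cannot store this slice")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = image.shape
    ds.PixelSpacing = [image.spacing[0], image.spacing[1]]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = 1
    ds.RescaleIntercept = 0
    ds.PixelData = hu.astype(np.int16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
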