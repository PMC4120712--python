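"""Reading CT slices into Hounsfield units and round-tripping ROI masks and results.

Every downstream stage works on the in-memory :class:`CTSlice` / :class:`ROIMask`
types defined here; nothing else in the package touches DICOM or image files.

Conventions: all geometry is 0-based ``(row, col)``; pixel pitch is a single
isotropic value in millimetres (anisotropic inputs are averaged with a warning,
since acquisitions in the intended pitch range 0.5-2.0 mm are near-isotropic).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import LesionMeasurement

logger = logging.getLogger(__name__)

__all__ = [
    "CTSlice",
    "ROIMask",
    "MetadataError",
    "UnsupportedInputError",
    "DimensionError",
    "read_ct_slice",
    "write_ct_slice",
    "read_roi_mask",
    "write_measurements",
]


class MetadataError(ValueError):
    """A required DICOM attribute (pixel spacing or rescale) is absent."""


class UnsupportedInputError(ValueError):
    """Input is not a single-frame CT image."""


class DimensionError(ValueError):
    """Mask and slice shapes disagree."""


@dataclass(frozen=True)
class CTSlice:
    """A single CT slice in Hounsfield units with its physical pixel pitch.

    Parameters
    ----------
    pixels : ndarray
        2-D float array of attenuation in HU (water = 0, air = -1024).
    pixel_pitch : float
        Isotropic pixel spacing in mm; must be positive.
    source_id : str
        Free-text provenance label carried into the measurement table.
    """

    pixels: np.ndarray
    pixel_pitch: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={px.ndim}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite-valued")
        object.__setattr__(self, "pixels", px)
        if not self.pixel_pitch > 0:
            raise ValueError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")
        if not 0.5 <= self.pixel_pitch <= 2.0:
            logger.warning(
                "pixel_pitch %.4f mm outside the expected 0.5-2.0 mm range",
                self.pixel_pitch,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ROIMask:
    """Binary region-of-interest (here: the manually segmented liver)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2-D, got ndim={m.ndim}")
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# DICOM input
# ---------------------------------------------------------------------------

def read_ct_slice(path: str | Path) -> CTSlice:
    """Read a single-frame CT DICOM file and convert stored values to HU.

    HU = stored * RescaleSlope + RescaleIntercept. The pixel pitch is the row
    spacing from ``PixelSpacing``; if row and column spacings differ, their
    arithmetic mean is used and a warning is logged.

    Raises
    ------
    MetadataError
        If ``PixelSpacing``, ``RescaleSlope`` or ``RescaleIntercept`` is absent.
    UnsupportedInputError
        If the file holds more than one frame.
    """
    ds = pydicom.dcmread(str(path))
    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames != 1:
        raise UnsupportedInputError(
            f"{path}: multi-frame input ({n_frames} frames) is not supported"
        )
    for attr in ("PixelSpacing", "RescaleSlope", "RescaleIntercept"):
        if getattr(ds, attr, None) is None:
            raise MetadataError(f"{path}: required DICOM attribute {attr} is missing")

    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    if abs(row_sp - col_sp) > 1e-9:
        pitch = 0.5 * (row_sp + col_sp)
        logger.warning(
            "anisotropic pixel spacing %.4f x %.4f mm; using mean %.4f mm",
            row_sp,
            col_sp,
            pitch,
        )
    else:
        pitch = row_sp

    hu = ds.pixel_array.astype(float) * float(ds.RescaleSlope) + float(
        ds.RescaleIntercept
    )
    return CTSlice(pixels=hu, pixel_pitch=pitch, source_id=Path(path).stem)


def write_ct_slice(ct: CTSlice, path: str | Path) -> None:
    """Write a CTSlice as a minimal single-frame CT DICOM file.

    Stored values are ``HU + 1024`` as unsigned 16-bit with slope 1 and
    intercept -1024, so ``read_ct_slice`` round-trips integer-HU pixels
    exactly. Intended for fixtures and phantom export, not clinical use.
    """
    hu = np.rint(ct.pixels).astype(np.int64)
    stored = hu + 1024
    if stored.min() < 0 or stored.max() > 65535:
        raise ValueError("HU range not representable as uint16 with intercept -1024")

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = ct.pixels.shape
    ds.PixelSpacing = [f"{ct.pixel_pitch:.6f}", f"{ct.pixel_pitch:.6f}"]
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "-1024"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = stored.astype("<u2").tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------

def read_roi_mask(path: str | Path, ct: CTSlice) -> ROIMask:
    """Read a liver ROI mask and validate its shape against the slice.

    Accepts PNG/TIFF images (nonzero = inside) or a JSON sidecar
    ``{"shape": [rows, cols], "data": "<raw file>", "dtype": "uint8"}``
    pointing at a raw binary dump next to it.

    An all-zero mask is accepted here; emptiness is an error only when the
    mask is used for measurement.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        sidecar = json.loads(path.read_text())
        raw = (path.parent / sidecar["data"]).read_bytes()
        arr = np.frombuffer(raw, dtype=np.dtype(sidecar.get("dtype", "uint8")))
        arr = arr.reshape(tuple(sidecar["shape"]))
    else:
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:  # collapse RGB(A): any nonzero channel counts
            arr = arr[..., :3].max(axis=-1)
    if arr.shape != ct.shape:
        raise DimensionError(
            f"mask shape {arr.shape} does not match slice shape {ct.shape}"
        )
    return ROIMask(mask=arr != 0)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = (
    "source_id",
    "lesion_index",
    "area_cm2",
    "max_diameter_cm",
    "centroid_row",
    "centroid_col",
)


def write_measurements(
    measurements: Sequence["LesionMeasurement"],
    path: str | Path,
    source_id: str = "",
) -> None:
    """Write lesion measurements to CSV in a deterministic order.

    Rows are sorted by descending area, ties broken by centroid row then
    column. An empty list yields a header-only file.
    """
    rows = [
        {
            "source_id": source_id,
            "lesion_index": m.label,
            "area_cm2": m.area_cm2,
            "max_diameter_cm": m.max_diameter_cm,
            "centroid_row": m.centroid[0],
            "centroid_col": m.centroid[1],
        }
        for m in measurements
    ]
    df = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    if len(df):
        df = df.sort_values(
            ["area_cm2", "centroid_row", "centroid_col"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    df.to_csv(path, index=False)
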