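"""Shared fixtures: synthetic DICOM writers and small phantom helpers.

All fixture files are generated at test time; nothing binary ships with
the repository.
"""

from __future__ import annotations

import numpy as np
import pytest
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid


def make_dicom(
    path,
    stored: np.ndarray,
    slope: float = 1.0,
    intercept: float = -1024.0,
    spacing: tuple[float, float] = (0.80, 0.80),
    omit: tuple[str, ...] = (),
    n_frames: int | None = None,
) -> None:
    """Write a minimal single-frame CT DICOM fixture with uint16 pixel data.

    ``omit`` drops attributes to provoke metadata errors; ``n_frames`` sets
    NumberOfFrames to fake a multi-frame file.
    """
    stored = np.asarray(stored, dtype="<u2")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = stored.shape
    ds.PixelSpacing = [f"{spacing[0]:.6f}", f"{spacing[1]:.6f}"]
    ds.RescaleSlope = str(slope)
    ds.RescaleIntercept = str(intercept)
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    if n_frames is not None:
        ds.NumberOfFrames = n_frames
    ds.PixelData = stored.tobytes()
    for attr in omit:
        delattr(ds, attr)
    ds.save_as(str(path), enforce_file_format=True)


@pytest.fixture
def dicom_factory(tmp_path):
    """Callable writing a DICOM fixture into tmp_path and returning its path."""

    counter = {"n": 0}

    def _make(**kwargs):
        counter["n"] += 1
        path = tmp_path / f"fixture_{counter['n']}.dcm"
        stored = kwargs.pop(
            "stored", np.full((8, 8), 1079, dtype=np.uint16)
        )
        make_dicom(path, stored, **kwargs)
        return path

    return _make


@pytest.fixture
def full_roi():
    """Factory for an all-true ROI matching a given shape."""
    from hccwave import ROIMask

    def _make(shape):
        return ROIMask(mask=np.ones(shape, dtype=bool))

    return _make
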