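"""From denoised HU image to measured enhanced-lesion regions.

The chain is: strict-inequality threshold -> 3x3 binary opening (erosion
then dilation, removing specks smaller than the structuring element and
smoothing boundaries) -> 8-connected components inside the liver ROI ->
per-component area and maximum Feret (caliper) diameter, the quantity
mRECIST response assessment is based on.

Diameter convention: the maximum centre-to-centre distance over boundary
pixels plus one pixel pitch, so both end pixels contribute their full
extent and a single pixel has diameter one pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .ct_io import CTSlice, DimensionError, ROIMask
from .intensity_model import (
    TissueIntensityModel,
    binarization_threshold,
    default_model,
)
from .wavelet_mra import MRAConfig, decompose, reconstruct_approximation

__all__ = [
    "BinaryImage",
    "LesionMeasurement",
    "SegmentationConfig",
    "EmptyMaskError",
    "binarize",
    "erode3x3",
    "dilate3x3",
    "morphological_open",
    "extract_lesions",
    "max_feret_diameter",
    "run_pipeline",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


class EmptyMaskError(ValueError):
    """The ROI contains no pixels, so nothing can be measured."""


@dataclass(frozen=True)
class BinaryImage:
    """A binary mask tied to the physical pixel pitch of its source slice."""

    mask: np.ndarray
    pixel_pitch: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2-D, got ndim={m.ndim}")
        object.__setattr__(self, "mask", m.astype(bool))
        if not self.pixel_pitch > 0:
            raise ValueError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")


@dataclass(frozen=True)
class LesionMeasurement:
    """One connected enhanced component with its physical measurements.

    ``area_cm2`` is pixel_count * (pitch/10)^2; ``max_diameter_cm`` the
    maximum Feret diameter. ``boundary_pixels`` are the component pixels
    with at least one 4-neighbour outside the component (or on the image
    edge), as (row, col) pairs.
    """

    label: int
    pixel_count: int
    area_cm2: float
    max_diameter_cm: float
    centroid: tuple[float, float]
    boundary_pixels: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the segmentation stage.

    threshold_sd_multiplier : float
        Multiplier m in threshold = mu_normal + m * sd_normal (default 1.0;
        0.0 thresholds at the normal-tissue mean alone).
    min_pixels : int
        Components smaller than this after opening are discarded (default 4,
        a guard against residual specks).
    connectivity : int
        4 or 8 for component labelling (default 8).
    boundary_convention : str
        'zero' treats out-of-bounds neighbours as background during
        morphology (masks shrink at the image border); 'reflect' mirrors
        the mask instead.
    """

    threshold_sd_multiplier: float = 1.0
    min_pixels: int = 4
    connectivity: int = 8
    boundary_convention: str = "zero"

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.boundary_convention not in ("zero", "reflect"):
            raise ValueError(
                f"boundary_convention must be 'zero' or 'reflect', "
                f"got {self.boundary_convention!r}"
            )


def binarize(image: np.ndarray, threshold: float, pitch: float) -> BinaryImage:
    """Pixelwise strict threshold: mask = image > threshold."""
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    return BinaryImage(mask=np.asarray(image) > threshold, pixel_pitch=pitch)


def _morph(b: BinaryImage, op, convention: str) -> BinaryImage:
    if convention == "reflect":
        m = np.pad(b.mask, 1, mode="reflect")
        out = op(m, structure=_SQUARE3)[1:-1, 1:-1]
    else:  # out-of-bounds neighbours are 0
        out = op(b.mask, structure=_SQUARE3, border_value=0)
    return BinaryImage(mask=out, pixel_pitch=b.pixel_pitch)


def erode3x3(b: BinaryImage, boundary_convention: str = "zero") -> BinaryImage:
    """Binary erosion with a 3x3 square: 1 iff the whole neighbourhood is 1."""
    return _morph(b, ndimage.binary_erosion, boundary_convention)


def dilate3x3(b: BinaryImage, boundary_convention: str = "zero") -> BinaryImage:
    """Binary dilation with a 3x3 square: 1 iff any neighbour is 1."""
    return _morph(b, ndimage.binary_dilation, boundary_convention)


def morphological_open(b: BinaryImage, boundary_convention: str = "zero") -> BinaryImage:
    """3x3 opening (erosion then dilation).

    Removes every connected component that contains no full 3x3 square and
    smooths the boundaries of those that remain; anti-extensive and
    idempotent.
    """
    return dilate3x3(erode3x3(b, boundary_convention), boundary_convention)


# ---------------------------------------------------------------------------
# Component measurement
# ---------------------------------------------------------------------------

def _boundary_pixels(component: np.ndarray) -> np.ndarray:
    """(row, col) pixels of `component` with a 4-neighbour outside it."""
    interior = ndimage.binary_erosion(
        component, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return np.argwhere(component & ~interior)


def max_feret_diameter(boundary: np.ndarray, pitch: float) -> float:
    """Maximum Feret (caliper) diameter of a pixel set, in cm.

    Maximum pairwise Euclidean centre-to-centre distance over the boundary
    pixels, plus one pixel pitch as end-correction, converted from mm to cm.
    The pairwise maximum is attained on the convex hull, which is used to
    cut the candidate set before the exact all-pairs scan.
    """
    pts = np.asarray(boundary, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("boundary must be a non-empty (n, 2) pixel array")
    if pts.shape[0] > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear sets: fall through to the all-pairs scan
    diff = pts[:, None, :] - pts[None, :, :]
    max_px = float(np.sqrt((diff**2).sum(-1)).max())
    return (max_px + 1.0) * pitch / 10.0


def extract_lesions(
    b: BinaryImage,
    roi: ROIMask,
    min_pixels: int = 4,
    connectivity: int = 8,
) -> list[LesionMeasurement]:
    """Measure the connected components of (mask AND roi).

    Components with fewer than ``min_pixels`` pixels are discarded; the rest
    are returned in descending pixel-count order (ties by centroid row then
    column). Raises :class:`EmptyMaskError` for an empty ROI and
    :class:`DimensionError` on shape mismatch.
    """
    if roi.shape != b.mask.shape:
        raise DimensionError(
            f"ROI shape {roi.shape} does not match mask shape {b.mask.shape}"
        )
    if not roi.mask.any():
        raise EmptyMaskError("ROI mask is empty; nothing to measure")

    inside = b.mask & roi.mask
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(inside, structure=structure)

    out: list[LesionMeasurement] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        count = int(comp.sum())
        if count < min_pixels:
            continue
        rows, cols = np.nonzero(comp)
        boundary = _boundary_pixels(comp)
        out.append(
            LesionMeasurement(
                label=lab,
                pixel_count=count,
                area_cm2=count * (b.pixel_pitch / 10.0) ** 2,
                max_diameter_cm=max_feret_diameter(boundary, b.pixel_pitch),
                centroid=(float(rows.mean()), float(cols.mean())),
                boundary_pixels=boundary,
            )
        )
    out.sort(key=lambda m: (-m.pixel_count, m.centroid[0], m.centroid[1]))
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    ct: CTSlice,
    roi: ROIMask,
    model: TissueIntensityModel | None = None,
    mra: MRAConfig | None = None,
    seg: SegmentationConfig | None = None,
) -> list[LesionMeasurement]:
    """Measure contrast-enhanced lesions in one CT slice.

    Stages: level-J approximation-only wavelet reconstruction of the whole
    slice -> strict threshold at mu_normal + m*sd_normal -> 3x3 opening ->
    8-connected components inside the ROI -> per-lesion maximum Feret
    diameter. Deterministic given its inputs; lesions are returned largest
    first.
    """
    if model is None:
        model = default_model()
    if mra is None:
        mra = MRAConfig()
    if seg is None:
        seg = SegmentationConfig()

    smoothed = reconstruct_approximation(decompose(ct.pixels, mra))
    threshold = binarization_threshold(model, seg.threshold_sd_multiplier)
    binary = binarize(smoothed, threshold, ct.pixel_pitch)
    opened = morphological_open(binary, seg.boundary_convention)
    return extract_lesions(
        opened, roi, min_pixels=seg.min_pixels, connectivity=seg.connectivity
    )
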