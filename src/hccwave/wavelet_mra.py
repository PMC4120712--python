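"""2-D discrete wavelet multiresolution analysis (MRA) for CT denoising.

The separable decimated DWT splits an image, level by level, into one
low-pass approximation plane C_J and three oriented detail planes d_j(q)
per level (q in {0deg, 90deg, 45deg}). Reconstruction from the level-J
approximation alone — all detail planes zeroed — suppresses fluctuations
smaller than roughly 2^J pixels while leaving larger structures (tumor-scale
enhancement) intact; that smoothed image is what the segmentation stage
thresholds.

The default configuration is the Daubechies-10 orthogonal wavelet at level
J = 2 with symmetric (half-sample) boundary padding. The wavelet's nominal
pseudo-frequency xi0 ~= 0.693 cycles/sample maps a level s to a physical
band via

    xi_s = xi0 / (2^s * p)        [mm^-1, p = pixel pitch in mm]

which is used for band reporting only; filtering always uses the named
wavelet's actual filter bank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "MRAConfig",
    "MRADecomposition",
    "LevelError",
    "decompose",
    "reconstruct",
    "reconstruct_approximation",
    "band_center_frequency",
]

#: detail-plane orientation labels, in storage order
QUADRANTS = ("0deg", "90deg", "45deg")


class LevelError(ValueError):
    """Requested decomposition level exceeds what the image size permits."""


@dataclass(frozen=True)
class MRAConfig:
    """Configuration of the multiresolution decomposition.

    Parameters
    ----------
    wavelet_name : str
        Mother wavelet (PyWavelets identifier). Default ``"db10"``,
        the orthogonal Daubechies wavelet with 10 vanishing moments.
    pseudo_frequency : float
        Nominal centre frequency xi0 of the mother wavelet in cycles/sample;
        metadata for band reporting, default 0.693.
    level : int
        Decomposition level J >= 1, default 2.
    boundary_mode : str
        PyWavelets signal-extension mode, default ``"symmetric"``
        (half-sample reflection), which minimises edge artefacts that would
        corrupt diameter measurement at the ROI border.
    """

    wavelet_name: str = "db10"
    pseudo_frequency: float = 0.693
    level: int = 2
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError(f"level must be >= 1, got {self.level}")
        if not 0.0 < self.pseudo_frequency < 1.0:
            raise ValueError(
                f"pseudo_frequency must lie in (0, 1), got {self.pseudo_frequency}"
            )
        if self.pseudo_frequency > 0.5:
            # warnings (not logging) so repeated construction dedups the message
            warnings.warn(
                f"pseudo_frequency {self.pseudo_frequency:.3f} cycles/sample exceeds "
                "the Nyquist rate 0.5; kept as nominal band-reporting metadata",
                stacklevel=2,
            )
        pywt.Wavelet(self.wavelet_name)  # validates the identifier


@dataclass(frozen=True)
class MRADecomposition:
    """Decimated 2-D DWT coefficients.

    ``approximation`` is the level-J plane C_J; ``details[j]`` holds the
    three oriented planes of level j+1 keyed ``"0deg"`` (HL), ``"90deg"``
    (LH) and ``"45deg"`` (HH), finest level first (details[0] is level 1).
    """

    approximation: np.ndarray
    details: tuple[dict, ...]
    config: MRAConfig
    original_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.details) != self.config.level:
            raise ValueError(
                f"expected {self.config.level} detail levels, got {len(self.details)}"
            )
        for lvl in self.details:
            if set(lvl) != set(QUADRANTS):
                raise ValueError(f"detail level keys {set(lvl)} != {set(QUADRANTS)}")


def _check_size(shape: tuple[int, int], level: int) -> None:
    min_side = min(shape)
    if min_side < 2**level:
        max_level = max(int(np.floor(np.log2(min_side))), 0)
        raise LevelError(
            f"image of shape {shape} is too small for level {level}; "
            f"maximum feasible level is {max_level}"
        )


def decompose(image: np.ndarray, config: MRAConfig | None = None) -> MRADecomposition:
    """Separable row/column filtering with per-level decimation.

    Lossless with :func:`reconstruct`. The image must measure at least
    2^J pixels along each dimension.
    """
    if config is None:
        config = MRAConfig()
    image = np.asarray(image, dtype=float)
    _check_size(image.shape, config.level)

    coeffs = pywt.wavedec2(
        image, config.wavelet_name, mode=config.boundary_mode, level=config.level
    )
    # pywt orders (cA_J, (cH_J, cV_J, cD_J), ..., (cH_1, cV_1, cD_1));
    # cV (high-pass along columns) is the 0deg quadrant, cH the 90deg, cD 45deg.
    details = tuple(
        {"0deg": cV, "90deg": cH, "45deg": cD} for (cH, cV, cD) in coeffs[:0:-1]
    )
    return MRADecomposition(
        approximation=coeffs[0],
        details=details,
        config=config,
        original_shape=image.shape,
    )


def _to_pywt(decomp: MRADecomposition, zero_details: bool) -> list:
    coeffs: list = [decomp.approximation]
    for lvl in reversed(decomp.details):
        cH, cV, cD = lvl["90deg"], lvl["0deg"], lvl["45deg"]
        if zero_details:
            cH, cV, cD = (np.zeros_like(c) for c in (cH, cV, cD))
        coeffs.append((cH, cV, cD))
    return coeffs


def _invert(decomp: MRADecomposition, zero_details: bool) -> np.ndarray:
    cfg = decomp.config
    out = pywt.waverec2(
        _to_pywt(decomp, zero_details), cfg.wavelet_name, mode=cfg.boundary_mode
    )
    r, c = decomp.original_shape
    return out[:r, :c]  # odd dimensions: the transform pads, we crop back


def reconstruct(decomp: MRADecomposition) -> np.ndarray:
    """Full inverse transform; reproduces the input to ~1e-8 relative error."""
    return _invert(decomp, zero_details=False)


def reconstruct_approximation(decomp: MRADecomposition) -> np.ndarray:
    """Inverse transform with every detail plane at levels 1..J zeroed.

    This is the denoised image handed to binarization: fluctuations on
    scales below ~2^J pixels are removed, structures larger than that are
    preserved. Output shape equals the original image shape. The operation
    is linear in the decomposed image.
    """
    return _invert(decomp, zero_details=True)


def band_center_frequency(
    pseudo_frequency: float, level: int | float, pixel_pitch: float
) -> float:
    """Centre spatial frequency (mm^-1) of the wavelet band at a given level.

    ``pseudo_frequency / (2**level * pixel_pitch)``; halves with each
    additional level. With the default xi0 = 0.693, level 2 and a 0.80 mm
    pitch this evaluates to ~0.217 mm^-1.
    """
    if pseudo_frequency <= 0 or pixel_pitch <= 0 or level < 0:
        raise ValueError("pseudo_frequency and pixel_pitch must be > 0, level >= 0")
    return pseudo_frequency / (2.0**level * pixel_pitch)
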