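"""Two-Gaussian model of normal vs. contrast-enhanced liver attenuation.

On arterial-phase CT, normal liver parenchyma and viable (enhancing) HCC
tissue have well-separated, approximately Gaussian HU histograms: about
55 +/- 10 HU for normal tissue and 90 +/- 11 HU for enhanced tumor. The model
supplies the global binarization threshold used by the segmentation stage,

    threshold = mu_normal + threshold_sd_multiplier * sd_normal

with multiplier 1 by default (65 HU for the default model); multiplier 0
thresholds at the normal mean alone.

When labelled tissue regions are unavailable, :func:`fit_two_gaussians`
estimates the model from the pooled ROI histogram with a two-component
Gaussian mixture (EM). The fixed :func:`default_model` remains the pipeline
default; the mixture fit is opt-in.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "TissueIntensityModel",
    "DegenerateFitError",
    "default_model",
    "fit_two_gaussians",
    "binarization_threshold",
]


class DegenerateFitError(ValueError):
    """Mixture fit collapsed or the data do not support two components."""


@dataclass(frozen=True)
class TissueIntensityModel:
    """Gaussian (mean, SD) pairs for normal and contrast-enhanced tissue, in HU.

    ``weight_contrast`` is the mixing proportion of the enhanced component;
    it is estimated by the mixture fit and otherwise purely descriptive.
    """

    mu_normal: float
    sd_normal: float
    mu_contrast: float
    sd_contrast: float
    weight_contrast: float = 0.5

    def __post_init__(self) -> None:
        if not (self.sd_normal > 0 and self.sd_contrast > 0):
            raise ValueError("component SDs must be positive")
        if not self.mu_contrast > self.mu_normal:
            raise ValueError(
                f"enhanced tissue must be brighter: mu_contrast={self.mu_contrast} "
                f"<= mu_normal={self.mu_normal}"
            )
        if not 0.0 <= self.weight_contrast <= 1.0:
            raise ValueError("weight_contrast must lie in [0, 1]")

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "TissueIntensityModel":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        return cls(**json.loads(text))


def default_model() -> TissueIntensityModel:
    """The reference attenuation model: normal 55 +/- 10 HU, enhanced 90 +/- 11 HU."""
    return TissueIntensityModel(
        mu_normal=55.0,
        sd_normal=10.0,
        mu_contrast=90.0,
        sd_contrast=11.0,
        weight_contrast=0.5,
    )


def fit_two_gaussians(
    values: Sequence[float] | np.ndarray,
    init: TissueIntensityModel | None = None,
    random_state: int = 0,
) -> TissueIntensityModel:
    """Maximum-likelihood two-component Gaussian mixture fit to HU values.

    EM runs until successive log-likelihoods differ by < 1e-8 (per sample) or
    500 iterations. Components are relabelled so ``mu_normal < mu_contrast``
    regardless of initialization order.

    Raises
    ------
    DegenerateFitError
        If a component SD collapses below 0.5 HU, or if the fitted component
        means are separated by less than the sum of the component SDs (the
        mixture is then effectively unimodal) — in either case the data are
        single-component and the fixed default model (or a single-Gaussian
        fit) should be used instead.
    ValueError
        If fewer than 100 values are supplied.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 100:
        raise ValueError(f"need at least 100 values to fit, got {x.size}")
    if init is None:
        init = default_model()

    w = init.weight_contrast
    gm = GaussianMixture(
        n_components=2,
        covariance_type="spherical",
        tol=1e-8,
        max_iter=500,
        weights_init=[1.0 - w, w] if 0 < w < 1 else None,
        means_init=[[init.mu_normal], [init.mu_contrast]],
        precisions_init=[1.0 / init.sd_normal**2, 1.0 / init.sd_contrast**2],
        random_state=random_state,
    )
    gm.fit(x[:, None])

    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    mu_n, mu_c = means[order]
    sd_n, sd_c = sds[order]
    w_c = weights[order][1]

    if min(sd_n, sd_c) < 0.5:
        raise DegenerateFitError(
            f"component SD collapsed to {min(sd_n, sd_c):.3g} HU (< 0.5 HU); "
            "the data look single-component — use a single-Gaussian fit"
        )
    if w_c >= 0.01 and (mu_c - mu_n) < (sd_n + sd_c):
        raise DegenerateFitError(
            f"fitted components overlap (means {mu_n:.1f} and {mu_c:.1f} HU, "
            f"SDs {sd_n:.1f}/{sd_c:.1f} HU); the data look single-component"
        )
    return TissueIntensityModel(
        mu_normal=float(mu_n),
        sd_normal=float(sd_n),
        mu_contrast=float(mu_c),
        sd_contrast=float(sd_c),
        weight_contrast=float(w_c),
    )


def binarization_threshold(
    model: TissueIntensityModel, sd_multiplier: float = 1.0
) -> float:
    """Binarization threshold in HU: ``mu_normal + sd_multiplier * sd_normal``."""
    return model.mu_normal + sd_multiplier * model.sd_normal
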