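# Methods

## Problem and model

After local therapy (typically transarterial chemoembolization), the
response of a hepatocellular carcinoma is assessed from the longest
diameter of its *viable* — arterially enhancing — tissue on a CT slice
(the mRECIST convention). `hccwave` measures that diameter
non-subjectively from a single Hounsfield-unit (HU) slice plus a manually
segmented liver mask.

The measurement rests on a two-Gaussian attenuation model for
arterial-phase liver: normal parenchyma at mean 55 HU with SD 10 HU, and
contrast-enhanced tumor tissue at mean 90 HU with SD 11 HU. The default
model hard-codes those values; `fit_two_gaussians` can re-estimate them
from an ROI histogram by a two-component EM mixture fit
(`sklearn.mixture.GaussianMixture`, log-likelihood tolerance 1e-8, at
most 500 iterations, components relabelled so the normal mean is the
lower one).

## Processing chain

1. **Denoising.** The slice is decomposed by a decimated separable 2-D
   DWT (Daubechies-10, `db10`, an orthogonal, asymmetric wavelet) to
   level J = 2 with symmetric (half-sample) boundary padding, and
   reconstructed from the level-2 approximation plane alone, all detail
   planes zeroed. This suppresses fluctuations below roughly
   2^J = 4 pixels (~3 mm at a 0.80 mm pitch) while leaving tumor-scale
   structure intact. The operation is linear and reduces background noise
   SD by roughly 4x.
2. **Thresholding.** Pixels strictly above
   `mu_normal + threshold_sd_multiplier * sd_normal` (default multiplier
   1.0, i.e. 65 HU) are marked enhanced. A multiplier of 0 thresholds at
   the normal mean alone; the default follows the stated
   mean-plus-one-SD rule.
3. **Opening.** Binary erosion then dilation with a 3x3 square
   structuring element removes components that contain no full 3x3
   square and smooths boundaries. Out-of-bounds neighbours count as
   background by default (masks shrink at the image border); a
   `reflect` convention is available, under which the
   erosion/dilation duality `dilate(b) = NOT erode(NOT b)` holds
   exactly.
4. **Measurement.** 8-connected components inside the liver ROI with at
   least `min_pixels = 4` pixels are measured: area
   `pixel_count * (pitch/10)^2` cm², and the maximum Feret (caliper)
   diameter — the largest centre-to-centre distance over boundary
   pixels, convex-hull-reduced for speed, plus one pixel pitch so that
   both end pixels contribute their extent and a single pixel has
   diameter one pitch. Lesions are returned largest first.

### Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `wavelet_name` | `db10` | — | mother wavelet of the MRA |
| `level` | 2 | — | decomposition depth J; smoothing scale 2^J px |
| `boundary_mode` | `symmetric` | — | DWT padding rule |
| `pseudo_frequency` | 0.693 | cycles/sample | nominal band-reporting ξ₀ |
| `threshold_sd_multiplier` | 1.0 | — | threshold = μ_n + m·σ_n |
| `min_pixels` | 4 | px | speck guard after opening |
| `connectivity` | 8 | — | component labelling |
| `pixel_pitch` | from DICOM | mm | physical scale of all measurements |

The band-frequency map ξ_s = ξ₀ / (2^s · p) reports the centre *spatial
frequency* of level s in mm⁻¹ (0.2166 mm⁻¹ ≈ 0.22 for ξ₀ = 0.693, s = 2,
p = 0.80 mm). Note the units: this is a frequency, not a length, and the
nominal ξ₀ = 0.693 slightly exceeds both the Nyquist rate (0.5) and the
computed `db10` centre frequency (0.684); it is kept as configuration
metadata for band reporting only and a warning is issued, while filtering
always uses the actual `db10` filter bank.

## Virtual phantom and validation sweep

The phantom emulates the intensity statistics of an arterial-phase liver
slice and nothing else: a 256 x 512 field at 0.80 mm pitch, background
iid N(55, 10²) HU, circular lesions iid N(90, 11²) HU, hard (non
anti-aliased) disk membership on pixel centres. It has no liver anatomy,
vessels, texture correlation, partial-volume edges or necrotic cores, so
passing the sweep shows the chain's geometric fidelity and noise
robustness under the stated intensity model — not performance on
patient images, where manual segmentation quality and heterogeneous
enhancement dominate.

The validation sweep runs single centred disks of true diameter 0.5 to
14.0 cm in 0.5 cm steps, 10 replicates each (280 runs), full-field ROI,
default configuration. Per-run RNG streams derive from the master seed by
a counter scheme, `numpy.random.default_rng([seed, run_index])`. The
sweep completes in a few seconds on one CPU. Agreement is summarized
Bland-Altman style on differences (true − measured): mean ± 2 SD limits
of agreement (the 2-SD convention; 1.96 is available via
`loa_multiplier`), OLS R² of measured on true, and a paired two-sided
t-test. Size-group summaries cut at 3 and 5 cm of the reference
diameter, the staging-relevant bounds.

## Numerical choices and degenerate inputs

- **Perfect reconstruction / Parseval.** The full inverse DWT reproduces
  any input (including odd dimensions, which the padded transform crops
  back) to 1e-8 relative error. Energy conservation of the orthogonal
  filter bank is exact only away from image borders under symmetric
  padding, so the Parseval property is asserted for boundary-free inputs
  (interior impulse, zero-margin patch).
- **Mixture-fit degeneracy.** The fit refuses data that do not support
  two components: a component SD collapsing below 0.5 HU, or fitted
  means closer than the sum of the component SDs (the mixture is then
  effectively unimodal). Both raise a fit error advising
  single-component treatment.
- **Ties and ordering.** Lesions are ordered by descending pixel count,
  then centroid row, then column; CSV rows by descending area with the
  same tie-break. All orderings are deterministic.
- **Empty inputs.** An empty ROI raises at measurement time (not at mask
  reading); a phantom with no lesion yields an empty lesion list; a
  missed sweep detection records 0.0 cm and logs rather than raising.
- **Anisotropic spacing.** Row/column spacings are averaged with a
  logged warning; all geometry assumes isotropic pitch.

## Measurement bias on the phantom

With the stated configuration the sweep shows a near-constant positive
offset of the measured diameter, ≈ +0.28 cm (≈ 3.5 px) independent of
disk size, with only ≈ 0.04 cm replicate spread, giving limits of
agreement of (true − measured) ≈ [−0.35, −0.21] cm and R² ≈ 1.0. The
offset decomposes as: the 65 HU threshold lies below the 72.5 HU
edge midpoint, placing the threshold contour of the smoothed edge about
0.9 px outside the true rim on each side (~0.14 cm on the diameter); the
one-pitch Feret end-correction (0.08 cm); and the max-statistic of
boundary noise (~0.05 cm). The offset is systematic and could be
calibrated out for a known tissue model, but the default pipeline
reports the uncorrected value. Raising the threshold to the edge
midpoint removes most of the offset at the cost of sensitivity to weakly
enhancing tissue.

## Known limitations

- Single-slice only; no volume or multi-slice diameter tracking.
- The liver ROI must be supplied; no automatic segmentation.
- The global threshold assumes spatially uniform enhancement statistics;
  no windowing is applied before analysis.
- Phantom realism is deliberately minimal (see above); agreement numbers
  from the sweep characterize the algorithm, not clinical accuracy.
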