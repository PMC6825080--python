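"""Grey-level normalization and quantization of masked ROIs.

The first step of the texture analysis limits the ROI grey levels to the
band mu +/- 3 sigma computed over the masked pixels (sigma is the
sample, n-1, standard deviation; values outside the band are clipped to
the nearer bound).  The clipped values are then linearly binned over
their own min-max range into ``Ng`` equal-width grey levels 1..Ng; cells
outside the mask are coded 0 and excluded from every downstream count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateROIError, ParameterError
from .synthetic import MIN_MASK_PIXELS, ROISample

__all__ = ["NormalizationResult", "QuantizedROI", "normalize_roi", "quantize", "crop_to_mask"]

DEFAULT_GREY_LEVELS = 64


@dataclass(frozen=True)
class NormalizationResult:
    """mu +/- 3 sigma clipped ROI values.

    ``values`` is a float array of the full (possibly cropped) frame;
    only entries under ``mask`` are meaningful.
    """

    mu: float
    sigma: float
    lower: float
    upper: float
    values: np.ndarray
    mask: np.ndarray

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass(frozen=True)
class QuantizedROI:
    """Integer grey levels 1..Ng inside the mask, 0 outside."""

    levels: np.ndarray
    Ng: int
    n_pixels: int

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0


def crop_to_mask(sample: ROISample, pad: int = 0) -> ROISample:
    """Crop image and mask to the mask's bounding box (plus optional pad)."""
    rows = np.flatnonzero(sample.mask.any(axis=1))
    cols = np.flatnonzero(sample.mask.any(axis=0))
    r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, sample.mask.shape[0])
    c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, sample.mask.shape[1])
    from dataclasses import replace

    return replace(sample, image=sample.image[r0:r1, c0:c1], mask=sample.mask[r0:r1, c0:c1])


def normalize_roi(sample: ROISample) -> NormalizationResult:
    """Clip masked grey values into [mu - 3 sigma, mu + 3 sigma].

    mu and sigma are the mean and sample (ddof=1) standard deviation of
    the pre-clip masked pixels.  A constant ROI (sigma = 0) is rejected:
    no 6-sigma band can be defined.
    """
    vals = sample.image[sample.mask].astype(np.float64)
    if vals.size < MIN_MASK_PIXELS:
        raise ParameterError(f"mask must cover >= {MIN_MASK_PIXELS} pixels")
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=1))
    if sigma <= 0.0:
        raise DegenerateROIError("constant ROI: sigma is zero, mu +/- 3 sigma undefined")
    lower, upper = mu - 3.0 * sigma, mu + 3.0 * sigma
    values = sample.image.astype(np.float64).copy()
    values[sample.mask] = np.clip(values[sample.mask], lower, upper)
    return NormalizationResult(
        mu=mu, sigma=sigma, lower=lower, upper=upper, values=values, mask=sample.mask
    )


def quantize(norm: NormalizationResult, Ng: int = DEFAULT_GREY_LEVELS) -> QuantizedROI:
    """Linear-bin the clipped masked values into grey levels 1..Ng.

    Bins are equal-width over [min, max] of the clipped values and
    upper-half-open; the maximum value is forced into level Ng.
    """
    if Ng < 2:
        raise ParameterError("Ng must be >= 2")
    vals = norm.masked_values
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax - vmin <= 0.0:
        raise DegenerateROIError("zero grey-level range after clipping")
    levels = np.zeros(norm.values.shape, dtype=np.int32)
    scaled = (norm.values[norm.mask] - vmin) / (vmax - vmin) * Ng
    levels[norm.mask] = np.minimum(np.floor(scaled).astype(np.int32) + 1, Ng)
    return QuantizedROI(levels=levels, Ng=Ng, n_pixels=int(vals.size))
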