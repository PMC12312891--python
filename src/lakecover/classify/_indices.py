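"""Normalized-difference water index and threshold masking."""

from __future__ import annotations

import numpy as np

from ..grids import ShapeError, SpectralImage, ValidationError


def water_index(image: SpectralImage, green_band: int,
                nir_or_swir_band: int) -> np.ndarray:
    """(green - NIR/SWIR) / (green + NIR/SWIR) per pixel, in [-1, 1].

    Water is positive (green exceeds the strongly absorbed infrared);
    vegetation and bare ground come out negative.  Pixels with a zero
    denominator or under the nodata mask are NaN.
    """
    for b in (green_band, nir_or_swir_band):
        if not (0 <= b < image.band_count):
            raise ShapeError(
                f"band {b} out of range for a {image.band_count}-band image")
    g = image.values[:, :, green_band]
    n = image.values[:, :, nir_or_swir_band]
    denom = g + n
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(denom != 0, (g - n) / denom, np.nan)
    idx = idx.astype(np.float64)
    idx[image.mask] = np.nan
    return idx


def threshold_mask(index: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean lake mask: index >= threshold (NaN cells are False)."""
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    index = np.asarray(index, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        return (index >= threshold) & np.isfinite(index)
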