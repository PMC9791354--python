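"""Normalized-difference spectral indices on co-registered band grids.

All three classic band-ratio indices are the same operator

    ND(a, b) = (a − b) / (a + b)

applied to different band pairs: NDVI over (NIR, red) for vegetation
vigour, NDWI over (green, NIR) for open water, and NDSI over
(green, SWIR) for snow.  Cells where the denominator is zero carry no
physical index and are masked rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["BandGrid", "BandError", "normalized_difference", "ndvi", "ndwi", "ndsi", "write_index"]

#: Conventional band names this module understands.
STANDARD_BANDS = ("green", "red", "nir", "swir")


class BandError(KeyError):
    """A requested band is not present in the grid."""


@dataclass
class BandGrid:
    """Named co-registered reflectance-like grids with a shared nodata mask."""

    bands: dict[str, np.ndarray]
    mask: np.ndarray | None = None  # True = nodata

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("BandGrid needs at least one band")
        self.bands = {str(k): np.asarray(v, dtype=float) for k, v in self.bands.items()}
        shapes = {v.shape for v in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError(f"bands differ in shape: {sorted(shapes)}")
        self.shape = shapes.pop()
        if self.mask is None:
            self.mask = np.zeros(self.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.shape:
                raise ValueError("mask shape differs from band shape")
        for name, band in self.bands.items():
            if not np.isfinite(band[~self.mask]).all():
                raise ValueError(f"band {name!r} has non-finite values outside the mask")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise BandError(f"band {name!r} not present; have {sorted(self.bands)}")


def normalized_difference(a: str, b: str, bands: BandGrid) -> np.ma.MaskedArray:
    """(a − b)/(a + b) per cell; zero-denominator and nodata cells masked.

    The result lies in [−1, 1] wherever both bands are non-negative.
    """
    av, bv = bands[a], bands[b]
    denom = av + bv
    bad = bands.mask | (denom == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(bad, 0.0, (av - bv) / np.where(bad, 1.0, denom))
    return np.ma.MaskedArray(values, mask=bad)


def ndvi(bands: BandGrid) -> np.ma.MaskedArray:
    """Normalized Difference Vegetation Index: (NIR − red)/(NIR + red)."""
    return normalized_difference("nir", "red", bands)


def ndwi(bands: BandGrid) -> np.ma.MaskedArray:
    """Normalized Difference Water Index: (green − NIR)/(green + NIR)."""
    return normalized_difference("green", "nir", bands)


def ndsi(bands: BandGrid) -> np.ma.MaskedArray:
    """Normalized Difference Snow Index: (green − SWIR)/(green + SWIR)."""
    return normalized_difference("green", "swir", bands)


def write_index(index: np.ma.MaskedArray, path) -> None:
    """Write an index as a single-band float32 TIFF (masked cells → NaN)."""
    tifffile.imwrite(path, index.filled(np.nan).astype(np.float32))
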