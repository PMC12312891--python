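"""Core raster data structures shared across the package.

A scene is a multiband reflectance grid (:class:`SpectralImage`); a
classification result is a categorical grid (:class:`ClassMap`) over the
fixed project-wide code table (0 = nodata, 1 = water, 2 = vegetation,
3 = mudflat, 4 = sand).  Both carry a :class:`RasterHeader` with a minimal
affine georeferencing model (row 0 is the northernmost row, pixel indices
are 0-based) so that areas are always derived from the transform, never
hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Project-wide class codes.
NODATA = 0
WATER = 1
VEGETATION = 2
MUDFLAT = 3
SAND = 4

CLASS_CODES: tuple[int, ...] = (WATER, VEGETATION, MUDFLAT, SAND)
CLASS_NAMES: dict[int, str] = {
    NODATA: "nodata",
    WATER: "water",
    VEGETATION: "vegetation",
    MUDFLAT: "mudflat",
    SAND: "sand",
}
NAME_TO_CODE: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}

# Colour table for 8-bit class-map rasters (RGB per code).
CLASS_PALETTE: dict[int, tuple[int, int, int]] = {
    NODATA: (0, 0, 0),
    WATER: (31, 119, 180),
    VEGETATION: (44, 160, 44),
    MUDFLAT: (140, 86, 75),
    SAND: (230, 218, 166),
}


class LakecoverError(Exception):
    """Base class for package errors."""


class ConfigurationError(LakecoverError, ValueError):
    """Invalid configuration or parameter value."""


class ShapeError(LakecoverError, ValueError):
    """Mismatched grid shapes or band counts."""


class ValidationError(LakecoverError, ValueError):
    """Invalid data content (codes, finiteness, emptiness)."""


@dataclass(frozen=True)
class RasterHeader:
    """Grid geometry plus georeferencing metadata.

    ``transform`` is the affine (a, b, c, d, e, f) mapping pixel
    (col, row) to world (x, y): x = c + a*col + b*row,
    y = f + d*col + e*row.  For north-up grids b = d = 0, a > 0, e < 0.
    """

    rows: int
    cols: int
    bands: int = 1
    dtype: str = "float32"
    nodata: float | None = None
    transform: tuple[float, float, float, float, float, float] = (
        30.0, 0.0, 0.0, 0.0, -30.0, 0.0,
    )
    crs: str = "EPSG:32650"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError("raster must have at least one row and column")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel size must be positive")

    @property
    def pixel_size(self) -> float:
        """Pixel edge length in meters (assumes square pixels)."""
        return float(abs(self.transform[0]))

    @property
    def pixel_area_km2(self) -> float:
        return self.pixel_size**2 / 1e6

    def with_bands(self, bands: int, dtype: str | None = None) -> "RasterHeader":
        return replace(self, bands=bands, dtype=dtype or self.dtype)


def _default_header(rows: int, cols: int, bands: int) -> RasterHeader:
    return RasterHeader(rows=rows, cols=cols, bands=bands)


@dataclass
class SpectralImage:
    """Dated multiband reflectance grid with a nodata mask.

    ``values`` has shape (rows, cols, bands); ``mask`` is True where the
    pixel carries no data.
    """

    values: np.ndarray
    date: str
    mask: np.ndarray | None = None
    header: RasterHeader = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ShapeError("spectral values must be (rows, cols, bands)")
        rows, cols, bands = self.values.shape
        if bands < 2:
            raise ShapeError("a spectral image needs at least 2 bands")
        if self.mask is None:
            self.mask = np.zeros((rows, cols), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (rows, cols):
                raise ShapeError("mask shape must match the grid")
        if self.header is None:
            self.header = _default_header(rows, cols, bands)
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValidationError("non-finite reflectance outside the nodata mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def band_count(self) -> int:
        return self.values.shape[2]

    @property
    def pixel_size(self) -> float:
        return self.header.pixel_size

    def flat_valid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (valid flat indices, n_bands-column sample matrix)."""
        valid = ~self.mask.ravel()
        flat = self.values.reshape(-1, self.band_count)
        return np.flatnonzero(valid), flat[valid]


@dataclass
class ClassMap:
    """Dated categorical grid over the project class codes."""

    labels: np.ndarray
    date: str
    header: RasterHeader = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ShapeError("class labels must be a 2-D grid")
        bad = set(np.unique(self.labels)) - ({NODATA} | set(CLASS_CODES))
        if bad:
            raise ValidationError(f"unknown class codes in map: {sorted(bad)}")
        if self.header is None:
            rows, cols = self.labels.shape
            self.header = RasterHeader(rows=rows, cols=cols, bands=1,
                                       dtype="uint8", nodata=NODATA)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        return self.labels == NODATA

    @property
    def pixel_size(self) -> float:
        return self.header.pixel_size

    def class_counts(self) -> dict[int, int]:
        return {code: int(np.count_nonzero(self.labels == code))
                for code in CLASS_CODES}


@dataclass
class TrainingSet:
    """Per-class labeled spectral samples.

    ``samples`` maps a class code to an (n_l, M) matrix; ``indices`` maps
    it to the flat pixel indices the samples were drawn from (may be empty
    for externally supplied samples).
    """

    samples: dict[int, np.ndarray]
    indices: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValidationError("a training set needs at least 2 classes")
        widths = set()
        for code, mat in self.samples.items():
            mat = np.atleast_2d(np.asarray(mat, dtype=np.float64))
            if mat.shape[0] < 2:
                raise ValidationError(
                    f"class {code} ({CLASS_NAMES.get(code, '?')}) has fewer than 2 samples")
            if not np.all(np.isfinite(mat)):
                raise ValidationError(f"non-finite training samples for class {code}")
            self.samples[code] = mat
            widths.add(mat.shape[1])
        if len(widths) != 1:
            raise ShapeError("all classes must share the same band count")
        seen: set[int] = set()
        for code, idx in self.indices.items():
            idx = np.asarray(idx)
            overlap = seen & set(idx.tolist())
            if overlap:
                raise ValidationError("class index sets must be disjoint")
            seen |= set(idx.tolist())

    @property
    def classes(self) -> list[int]:
        return sorted(self.samples)

    @property
    def band_count(self) -> int:
        return next(iter(self.samples.values())).shape[1]

    def counts(self) -> dict[int, int]:
        return {c: self.samples[c].shape[0] for c in self.classes}
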