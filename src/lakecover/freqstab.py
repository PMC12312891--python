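"""Pixel-wise multi-year analytics.

Class maps are binarized per target class, reduced to one presence grid
per year (majority rule by default), accumulated into an inundation /
vegetation frequency raster, binned into named frequency categories on
half-open intervals, and summarized as a per-pixel coefficient of
variation (population divisor) mapped to ordered stability categories.
Cross-period change is reported as a land-category transfer matrix in
km² with Total / Decreasing / Increasing marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import (
    CLASS_CODES,
    CLASS_NAMES,
    ClassMap,
    ConfigurationError,
    NODATA,
    ShapeError,
    ValidationError,
)

WATER_BIN_NAMES = ("low", "medium", "relatively high", "high")
VEGETATION_BIN_NAMES = ("low", "relatively low", "medium", "high")
DEFAULT_BIN_EDGES = (0, 3, 5, 7, 9)  # (0,3], (3,5], (5,7], (7,9]


def binarize(class_map: ClassMap, target: int) -> np.ndarray:
    """Indicator grid (int8): 1 where the pixel has the target class,
    0 elsewhere, -1 under nodata."""
    if target not in CLASS_CODES:
        raise ValidationError(f"invalid target class code {target}")
    out = (class_map.labels == target).astype(np.int8)
    out[class_map.mask] = -1
    return out


def _stack(grids) -> np.ndarray:
    arrs = [np.asarray(g) for g in grids]
    if not arrs:
        raise ValidationError("need at least one grid")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ShapeError("all grids must share one shape")
    return np.stack(arrs).astype(np.float64)


def annual_presence(indicators, rule: str = "majority") -> np.ndarray:
    """Reduce one year's scene indicators to a 0/1 presence grid.

    ``majority``: present when the mean indicator is >= 0.5 (ties count
    as present).  ``any``: present when any scene shows the class.
    Nodata (-1) cells are excluded from the mean; all-nodata cells
    return -1.
    """
    stack = _stack(indicators)
    valid = stack >= 0
    n_valid = valid.sum(axis=0)
    total = np.where(valid, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_valid > 0, total / np.maximum(n_valid, 1), np.nan)
    if rule == "majority":
        present = mean >= 0.5
    elif rule == "any":
        present = total > 0
    else:
        raise ConfigurationError(f"unknown presence rule {rule!r}")
    out = np.where(present, 1, 0).astype(np.int8)
    out[n_valid == 0] = -1
    return out


@dataclass
class FrequencyRaster:
    """Per-pixel count of presence years for one target class."""

    counts: np.ndarray
    n_years: int
    target: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int16)
        valid = self.counts >= 0
        if valid.any() and self.counts[valid].max(initial=0) > self.n_years:
            raise ValidationError("counts cannot exceed the number of years")

    @property
    def mask(self) -> np.ndarray:
        return self.counts < 0


def accumulate_frequency(annual_grids, target: int = 0,
                         ) -> FrequencyRaster:
    """Sum the annual 0/1 presence grids into a frequency raster."""
    stack = _stack(annual_grids)
    n_years = stack.shape[0]
    valid = stack >= 0
    counts = np.where(valid, stack, 0.0).sum(axis=0).astype(np.int16)
    counts[~valid.any(axis=0)] = -1
    return FrequencyRaster(counts=counts, n_years=n_years, target=target)


@dataclass
class FrequencyClassMap:
    """Binned frequency categories; 0 = null (never present), 1..4 = bins."""

    categories: np.ndarray
    names: tuple[str, ...]
    edges: tuple[int, ...]

    @property
    def mask(self) -> np.ndarray:
        return self.categories < 0


def classify_frequency(freq: FrequencyRaster,
                       scheme: str = "water",
                       edges: tuple[int, ...] = DEFAULT_BIN_EDGES,
                       ) -> FrequencyClassMap:
    """Bin counts on half-open intervals (left-open, right-closed).

    With the default edges: (0,3] -> bin 1, (3,5] -> 2, (5,7] -> 3,
    (7,9] -> 4; a count of 0 maps to null (category 0).
    """
    if scheme == "water":
        names = WATER_BIN_NAMES
    elif scheme == "vegetation":
        names = VEGETATION_BIN_NAMES
    else:
        raise ConfigurationError(f"unknown frequency scheme {scheme!r}")
    if list(edges) != sorted(set(edges)):
        raise ConfigurationError("bin edges must be strictly increasing")
    n_bins = len(edges) - 1
    if n_bins != len(names):
        names = tuple(f"bin{i+1}" for i in range(n_bins))
    counts = freq.counts
    valid = counts >= 0
    if valid.any() and counts[valid].max(initial=0) > edges[-1]:
        raise ValidationError(
            f"counts exceed the top bin edge {edges[-1]}")
    cats = np.zeros(counts.shape, dtype=np.int8)
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        cats[(counts > lo) & (counts <= hi)] = i + 1
    cats[~valid] = -1
    return FrequencyClassMap(categories=cats, names=names,
                             edges=tuple(edges))


def frequency_share(fmap: FrequencyClassMap) -> dict:
    """Per-category proportions over non-null pixels plus the covered
    fraction of the analysis mask."""
    cats = fmap.categories
    valid = cats >= 0
    nonnull = cats > 0
    n_nonnull = int(nonnull.sum())
    if n_nonnull == 0:
        raise ValidationError("all pixels are null; shares undefined")
    shares = {
        name: float(np.count_nonzero(cats == i + 1) / n_nonnull)
        for i, name in enumerate(fmap.names)
    }
    covered = float(n_nonnull / valid.sum()) if valid.any() else float("nan")
    return {"shares": shares, "covered_fraction": covered,
            "n_nonnull": n_nonnull}


@dataclass
class CVRaster:
    """Per-pixel coefficient of variation of annual presence, in percent."""

    cv: np.ndarray
    mean_presence: np.ndarray
    n_years: int

    @property
    def mask(self) -> np.ndarray:
        return ~np.isfinite(self.cv)


def cv_map(annual_grids) -> CVRaster:
    """CV = sd(F_i) / mean(F_i) * 100 with the population divisor n.

    Pixels never present (mean 0) or outside the mask are NaN.
    """
    stack = _stack(annual_grids)
    if stack.shape[0] < 2:
        raise ValidationError("CV needs at least 2 annual grids")
    nodata = (stack < 0).any(axis=0)
    stack = np.where(stack < 0, 0.0, stack)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)  # population divisor n, ddof=0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean * 100.0, np.nan)
    cv[nodata] = np.nan
    return CVRaster(cv=cv, mean_presence=mean, n_years=stack.shape[0])


STABILITY_NAMES_3 = ("high", "medium", "low or relatively low")


@dataclass
class StabilityMap:
    """Ordered stability categories from CV (lower CV = higher stability)."""

    categories: np.ndarray
    names: tuple[str, ...]
    breaks: tuple[float, ...]

    def shares(self) -> dict[str, float]:
        valid = self.categories > 0
        n = int(valid.sum())
        if n == 0:
            raise ValidationError("no classified pixels")
        return {name: float(np.count_nonzero(self.categories == i + 1) / n)
                for i, name in enumerate(self.names)}


def tercile_breaks(cv: CVRaster) -> tuple[float, float]:
    """Default stability breaks: CV terciles over non-null pixels."""
    vals = cv.cv[np.isfinite(cv.cv)]
    if vals.size == 0:
        raise ValidationError("no defined CV values")
    q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
    if q2 <= q1:  # degenerate distribution (e.g. mostly zero CV)
        q2 = q1 + max(1e-9, abs(q1) * 1e-9)
    return float(q1), float(q2)


def stability_classes(cv: CVRaster,
                      breaks: tuple[float, ...] | None = None,
                      names: tuple[str, ...] | None = None) -> StabilityMap:
    """Bin CV into ordered stability categories (category 1 = most stable).

    ``breaks`` are the interior CV thresholds; ``None`` uses terciles.
    """
    if breaks is None:
        breaks = tercile_breaks(cv)
    if list(breaks) != sorted(breaks) or len(set(breaks)) != len(breaks):
        raise ConfigurationError("breaks must be strictly increasing")
    if names is None:
        if len(breaks) == 2:
            names = STABILITY_NAMES_3
        else:
            names = tuple(f"class_{i+1}" for i in range(len(breaks) + 1))
    if len(names) != len(breaks) + 1:
        raise ConfigurationError("need one more category name than breaks")
    cats = np.zeros(cv.cv.shape, dtype=np.int8)
    finite = np.isfinite(cv.cv)
    cats[finite] = np.digitize(cv.cv[finite], breaks, right=True) + 1
    return StabilityMap(categories=cats, names=tuple(names),
                        breaks=tuple(float(b) for b in breaks))


def modal_map(maps: list[ClassMap]) -> ClassMap:
    """Per-pixel most frequent label across a period; ties take the
    lowest class code, all-nodata pixels stay nodata."""
    if not maps:
        raise ValidationError("need at least one map")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ShapeError("all maps must share one shape")
    stack = np.stack([m.labels for m in maps])
    counts = np.zeros((len(CLASS_CODES) + 1, *shape), dtype=np.int32)
    for code in (NODATA, *CLASS_CODES):
        counts[code] = (stack == code).sum(axis=0)
    class_counts = counts[1:]
    best = np.argmax(class_counts, axis=0) + 1  # first max -> lowest code
    labels = best.astype(np.uint8)
    labels[class_counts.sum(axis=0) == 0] = NODATA
    return ClassMap(labels, date=maps[-1].date, header=maps[0].header)


@dataclass
class TransferMatrix:
    """Cross-period class-transfer areas in km² with marginals."""

    labels: list[int]
    areas: np.ndarray  # rows = origin classes, cols = destination classes

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=np.float64)
        k = len(self.labels)
        if self.areas.shape != (k, k):
            raise ShapeError("areas must be K x K")
        if np.any(self.areas < 0):
            raise ValidationError("transfer areas must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.areas.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.areas.sum(axis=0)

    @property
    def decreasing(self) -> np.ndarray:
        return self.row_totals - np.diag(self.areas)

    @property
    def increasing(self) -> np.ndarray:
        return self.col_totals - np.diag(self.areas)

    @property
    def grand_total(self) -> float:
        return float(self.areas.sum())

    def to_frame(self) -> pd.DataFrame:
        """Table layout: classes x classes plus Total/Decreasing columns
        and Total/Increasing rows."""
        names = [CLASS_NAMES.get(lab, str(lab)) for lab in self.labels]
        df = pd.DataFrame(self.areas, index=names, columns=names)
        df["Total"] = self.row_totals
        df["Decreasing"] = self.decreasing
        total_row = pd.Series(
            list(self.col_totals) + [self.grand_total, np.nan],
            index=df.columns, name="Total")
        inc_row = pd.Series(
            list(self.increasing) + [np.nan, np.nan],
            index=df.columns, name="Increasing")
        return pd.concat([df, total_row.to_frame().T, inc_row.to_frame().T])


def transfer_matrix(origin: ClassMap, destination: ClassMap) -> TransferMatrix:
    """Cross-tabulate origin vs destination labels into km² areas."""
    if origin.shape != destination.shape:
        raise ShapeError("origin and destination shapes differ")
    if origin.header.pixel_size != destination.header.pixel_size:
        raise ShapeError("origin and destination pixel sizes differ")
    valid = (origin.labels != NODATA) & (destination.labels != NODATA)
    labels = list(CLASS_CODES)
    k = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((k, k), dtype=np.int64)
    o = origin.labels[valid].ravel()
    d = destination.labels[valid].ravel()
    if o.size:
        np.add.at(counts, (o.astype(int) - 1, d.astype(int) - 1), 1)
    return TransferMatrix(labels=labels,
                          areas=counts * origin.header.pixel_area_km2)
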