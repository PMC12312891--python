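"""Area accounting and series statistics for classified scene stacks.

Per-scene class areas are derived from pixel counts and the raster's
affine pixel size; descriptive statistics, a two-sided Grubbs extreme
outlier test, Pearson correlations and calendar-year / calendar-month
share aggregation operate on the resulting dated series.  Mudflat and
sand are reported jointly (their sum) to match the three-way area
accounting convention, with the four-way breakdown available on records
built from class maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import (
    CLASS_CODES,
    MUDFLAT,
    SAND,
    VEGETATION,
    WATER,
    ClassMap,
    ValidationError,
)

logger = logging.getLogger(__name__)

CLASS_COLUMNS = ("water_km2", "vegetation_km2", "mudflat_sand_km2")


@dataclass
class AreaRecord:
    """Per-date class areas in km² (mudflat and sand reported jointly)."""

    date: str
    water_km2: float
    vegetation_km2: float
    mudflat_sand_km2: float
    mudflat_km2: float | None = None
    sand_km2: float | None = None

    def __post_init__(self) -> None:
        for name in CLASS_COLUMNS:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total_km2(self) -> float:
        return self.water_km2 + self.vegetation_km2 + self.mudflat_sand_km2


@dataclass
class AreaSeries:
    """Ordered, duplicate-free list of dated area records."""

    records: list[AreaRecord]
    source: str = "classified"

    def __post_init__(self) -> None:
        dates = [r.date for r in self.records]
        if any(a >= b for a, b in zip(dates, dates[1:])):
            raise ValidationError("record dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([{ "date": r.date, **{c: getattr(r, c) for c in CLASS_COLUMNS}}
                           for r in self.records])
        df["date"] = pd.to_datetime(df["date"])
        return df

    def column(self, cls: str) -> np.ndarray:
        col = _class_column(cls)
        return np.array([getattr(r, col) for r in self.records], dtype=float)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "csv") -> "AreaSeries":
        records = [
            AreaRecord(date=pd.Timestamp(row["date"]).strftime("%Y-%m-%d"),
                       water_km2=float(row["water_km2"]),
                       vegetation_km2=float(row["vegetation_km2"]),
                       mudflat_sand_km2=float(row["mudflat_sand_km2"]))
            for _, row in df.iterrows()
        ]
        return cls(records=records, source=source)


def _class_column(cls: str) -> str:
    aliases = {
        "water": "water_km2", "water_km2": "water_km2",
        "vegetation": "vegetation_km2", "vegetation_km2": "vegetation_km2",
        "mudflat_sand": "mudflat_sand_km2", "mudflat&sand": "mudflat_sand_km2",
        "mudflat_sand_km2": "mudflat_sand_km2",
    }
    if cls not in aliases:
        raise ValidationError(f"unknown class column {cls!r}")
    return aliases[cls]


def class_areas(class_map: ClassMap) -> AreaRecord:
    """Pixel counts times pixel area, in km², per class."""
    counts = class_map.class_counts()
    px = class_map.header.pixel_area_km2
    areas = {code: counts[code] * px for code in CLASS_CODES}
    return AreaRecord(
        date=class_map.date,
        water_km2=areas[WATER],
        vegetation_km2=areas[VEGETATION],
        mudflat_sand_km2=areas[MUDFLAT] + areas[SAND],
        mudflat_km2=areas[MUDFLAT],
        sand_km2=areas[SAND],
    )


def areas_from_maps(maps: list[ClassMap]) -> AreaSeries:
    records = sorted((class_areas(m) for m in maps), key=lambda r: r.date)
    return AreaSeries(records=records)


@dataclass
class DescriptiveStats:
    mean: float
    sd: float
    minimum: float
    maximum: float
    min_date: str
    max_date: str
    n: int


def descriptive_stats(series: AreaSeries, cls: str) -> DescriptiveStats:
    """Sample mean/sd (divisor n-1) and dated extremes for one class."""
    x = series.column(cls)
    if x.size < 2:
        raise ValidationError("need at least 2 records for a standard deviation")
    i_min, i_max = int(np.argmin(x)), int(np.argmax(x))
    return DescriptiveStats(
        mean=float(x.mean()), sd=float(x.std(ddof=1)),
        minimum=float(x[i_min]), maximum=float(x[i_max]),
        min_date=series.records[i_min].date,
        max_date=series.records[i_max].date,
        n=x.size,
    )


@dataclass
class GrubbsResult:
    statistic: float
    critical: float
    alpha: float
    n: int
    index: int
    outlier: bool
    p_value: float
    degenerate: bool = False


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    if n < 3:
        raise ValidationError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def grubbs(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided Grubbs extreme-outlier test with sample (n-1) sd.

    The statistic is ``max_i |x_i - mean| / sd``; the decision compares it
    with the t-based critical value at significance ``alpha``.  The
    reported p-value is the standard Grubbs tail probability (clipped to
    [0, 1]), a comparable analogue rather than an exact p.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError("Grubbs test needs n >= 3")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    s = x.std(ddof=1)
    mean = x.mean()
    if s == 0:
        return GrubbsResult(statistic=0.0, critical=grubbs_critical(n, alpha),
                            alpha=alpha, n=n, index=0, outlier=False,
                            p_value=1.0, degenerate=True)
    resid = np.abs(x - mean) / s
    idx = int(np.argmax(resid))
    g = float(resid[idx])
    crit = grubbs_critical(n, alpha)
    # invert the critical-value relation to get the G statistic's tail prob
    denom = (n - 1) ** 2 - g * g * n
    if denom <= 0:
        p = 0.0
    else:
        t_equiv = np.sqrt(g * g * n * (n - 2) / denom)
        p = min(1.0, 2.0 * n * float(stats.t.sf(t_equiv, n - 2)))
    return GrubbsResult(statistic=g, critical=crit, alpha=alpha, n=n,
                        index=idx, outlier=g > crit, p_value=p)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and its square."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("series must have equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for a constant series")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def series_correlations(series: AreaSeries) -> dict[tuple[str, str], float]:
    """Pairwise Pearson r between the three class-area columns."""
    cols = {c: series.column(c) for c in ("water", "vegetation", "mudflat_sand")}
    out = {}
    names = list(cols)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[(a, b)] = pearson(cols[a], cols[b])[0]
    return out


def _share_frame(series: AreaSeries) -> pd.DataFrame:
    df = series.to_frame()
    total = df[list(CLASS_COLUMNS)].sum(axis=1)
    if (total <= 0).any():
        raise ValidationError("every record must have positive total area")
    for c in CLASS_COLUMNS:
        df[c] = df[c] / total * 100.0
    return df


def annual_share(series: AreaSeries) -> pd.DataFrame:
    """Per-calendar-year unweighted mean of per-record class shares (%)."""
    df = _share_frame(series)
    df["year"] = df["date"].dt.year
    return df.groupby("year")[list(CLASS_COLUMNS)].mean()


def monthly_share(series: AreaSeries) -> pd.DataFrame:
    """Per-calendar-month (across years) mean class shares (%).

    Months with no records are present with NaN values.
    """
    df = _share_frame(series)
    df["month"] = df["date"].dt.month
    grouped = df.groupby("month")[list(CLASS_COLUMNS)].mean()
    return grouped.reindex(range(1, 13))
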