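"""Seeded synthetic basin scenes for end-to-end pipeline testing.

Generates a single-basin elevation model, a seasonal water-level series
peaking in summer, elevation-zoned ground-truth class maps and noisy
multiband reflectance scenes whose class signatures follow the usual
spectral ordering: water darkest in NIR/SWIR, vegetation dark in red and
bright in NIR, bare sediment intermediate, dry sand brightest.

All randomness flows from a single integer seed through named
``numpy.random.Generator`` streams, so a config reproduces its scenes
bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import (
    CLASS_CODES,
    CLASS_NAMES,
    MUDFLAT,
    SAND,
    VEGETATION,
    WATER,
    ClassMap,
    ConfigurationError,
    RasterHeader,
    SpectralImage,
    ValidationError,
    TrainingSet,
)

# Band layout of the default signature table: blue, green, red, NIR,
# SWIR1, SWIR2.  Index constants are used by the water-index helpers.
BAND_BLUE, BAND_GREEN, BAND_RED, BAND_NIR, BAND_SWIR1, BAND_SWIR2 = range(6)

DEFAULT_SIGNATURES: dict[int, tuple[float, ...]] = {
    WATER: (0.06, 0.08, 0.06, 0.03, 0.01, 0.01),
    VEGETATION: (0.04, 0.06, 0.04, 0.45, 0.25, 0.12),
    MUDFLAT: (0.08, 0.11, 0.13, 0.20, 0.25, 0.20),
    SAND: (0.15, 0.20, 0.25, 0.30, 0.35, 0.30),
}

_PEAK_MONTH = 7  # annual level maximum; within the June-September high stand


@dataclass
class SimulationConfig:
    """Parameters of the synthetic basin and its scene calendar."""

    grid_rows: int = 64
    grid_cols: int = 64
    n_years: int = 9
    scenes_per_year: int = 4
    band_count: int = 6
    signature_table: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURES))
    noise_sd: float = 0.01
    water_level_base: float = 4.0
    water_level_amplitude: float = 2.5
    interannual_sd: float = 0.3
    mudflat_band_width: float = 1.0
    vegetation_band_width: float = 2.0
    dem_relief: float = 10.0
    dem_noise_amplitude: float = 0.5
    sediment_visible_offset: float = 0.0
    start_year: int = 2013
    pixel_size: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if self.n_years < 1 or self.scenes_per_year < 1:
            raise ConfigurationError("n_years and scenes_per_year must be >= 1")
        if self.band_count < 2:
            raise ConfigurationError("band_count must be >= 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.mudflat_band_width < 0 or self.vegetation_band_width < 0:
            raise ConfigurationError("zonation band widths must be >= 0")
        for code, sig in self.signature_table.items():
            sig = tuple(float(v) for v in sig)
            if len(sig) != self.band_count:
                raise ConfigurationError(
                    f"signature for class {code} has {len(sig)} bands, "
                    f"expected {self.band_count}")
            if min(sig) < 0 or max(sig) > 1:
                raise ConfigurationError("reflectance means must lie in [0, 1]")
            self.signature_table[code] = sig
        self._check_signature_ordering()

    def _check_signature_ordering(self) -> None:
        sig = self.signature_table
        if not set(CLASS_CODES) <= set(sig):
            return  # partial tables are allowed; ordering checked when complete
        if self.band_count < 6:
            return
        if not sig[WATER][BAND_NIR] < sig[VEGETATION][BAND_NIR]:
            raise ConfigurationError("water NIR mean must be below vegetation NIR mean")
        if not sig[VEGETATION][BAND_RED] < sig[MUDFLAT][BAND_RED]:
            raise ConfigurationError("vegetation red mean must be below mudflat red mean")
        swir = {c: sig[c][BAND_SWIR1] for c in CLASS_CODES}
        if min(swir, key=swir.get) != WATER:
            raise ConfigurationError("water must have the minimum SWIR mean")

    def header(self, bands: int = 1, dtype: str = "float32") -> RasterHeader:
        p = self.pixel_size
        return RasterHeader(rows=self.grid_rows, cols=self.grid_cols,
                            bands=bands, dtype=dtype,
                            transform=(p, 0.0, 0.0, 0.0, -p, 0.0))

    def rng(self, stream: str) -> np.random.Generator:
        """Named child generator so each stage draws independently."""
        key = zlib.crc32(stream.encode("utf-8"))
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class ElevationGrid:
    """Single-basin elevation surface."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("elevation grid must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ScenePack:
    """A simulated stack of dated scenes with ground truth."""

    dem: ElevationGrid
    dates: list[str]
    levels: list[float]
    truths: list[ClassMap]
    images: list[SpectralImage]
    config: SimulationConfig

    def __post_init__(self) -> None:
        n = len(self.dates)
        if not (len(self.levels) == len(self.truths) == len(self.images) == n):
            raise ValidationError("scene lists must have equal length")
        if any(a >= b for a, b in zip(self.dates, self.dates[1:])):
            raise ValidationError("scene dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.dates)

    def scenes(self):
        return zip(self.dates, self.levels, self.truths, self.images)


def make_dem(config: SimulationConfig) -> ElevationGrid:
    """Smooth single-basin surface: radial bowl plus a low-frequency field.

    With ``dem_noise_amplitude = 0`` the surface is the pure bowl
    ``relief * (r / r_max)**2`` with its minimum at the grid center.
    """
    rows, cols = config.grid_rows, config.grid_cols
    if rows < 8 or cols < 8:
        raise ConfigurationError("DEM grid must be at least 8x8")
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    dist = np.hypot(rr - r0, cc - c0)
    bowl = config.dem_relief * (dist / dist.max()) ** 2
    if config.dem_noise_amplitude > 0:
        rng = config.rng("dem")
        noise = rng.standard_normal((rows, cols))
        noise = ndimage.gaussian_filter(noise, sigma=max(rows, cols) / 12.0,
                                        mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd * config.dem_noise_amplitude
        bowl = bowl + noise
    dem = ElevationGrid(bowl)
    lo, hi = dem.values.min(), dem.values.max()
    if not (lo < config.water_level_base < hi):
        raise ConfigurationError(
            "water_level_base must lie strictly inside the DEM elevation range "
            f"({lo:.2f}, {hi:.2f})")
    return dem


def _scene_months(scenes_per_year: int) -> list[int]:
    """Calendar months for one year, spread evenly and anchored on the peak.

    The spread always includes the peak month so the within-year argmax is
    deterministic and falls in the summer high stand for any scene count.
    """
    offsets = np.floor(np.linspace(0, 12, scenes_per_year, endpoint=False))
    months = sorted({int((_PEAK_MONTH - 1 + o) % 12) + 1 for o in offsets})
    return months


def water_level_series(config: SimulationConfig) -> list[tuple[str, float]]:
    """Dated water levels: sinusoid peaking mid-summer plus yearly anomalies."""
    rng = config.rng("levels")
    months = _scene_months(config.scenes_per_year)
    out: list[tuple[str, float]] = []
    for yi in range(config.n_years):
        year = config.start_year + yi
        anomaly = (rng.normal(0.0, config.interannual_sd)
                   if config.interannual_sd > 0 else 0.0)
        for month in months:
            phase = 2.0 * np.pi * (month - _PEAK_MONTH) / 12.0
            level = (config.water_level_base
                     + config.water_level_amplitude * np.cos(phase)
                     + anomaly)
            out.append((f"{year:04d}-{month:02d}-15", float(level)))
    return out


def render_truth(dem: ElevationGrid, level: float,
                 config: SimulationConfig) -> ClassMap:
    """Elevation-banded zonation: water below the waterline, then a mudflat
    fringe, then a vegetation belt, then sand above."""
    z = dem.values
    labels = np.full(z.shape, SAND, dtype=np.uint8)
    veg_top = level + config.mudflat_band_width + config.vegetation_band_width
    labels[z < veg_top] = VEGETATION
    labels[z < level + config.mudflat_band_width] = MUDFLAT
    labels[z < level] = WATER
    return ClassMap(labels, date="", header=config.header(dtype="uint8"))


def render_spectra(truth: ClassMap, config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> SpectralImage:
    """Class-mean spectra plus diagonal Gaussian noise, clipped to [0, 1]."""
    present = set(np.unique(truth.labels)) - {0}
    missing = present - set(config.signature_table)
    if missing:
        names = ", ".join(CLASS_NAMES.get(c, str(c)) for c in sorted(missing))
        raise ConfigurationError(f"no spectral signature for class(es): {names}")
    if rng is None:
        rng = config.rng("spectra")
    rows, cols = truth.shape
    m = config.band_count
    values = np.zeros((rows, cols, m), dtype=np.float64)
    for code in sorted(present):
        sig = np.asarray(config.signature_table[code])
        values[truth.labels == code] = sig
    if config.sediment_visible_offset > 0:
        water = truth.labels == WATER
        values[water, :min(3, m)] += config.sediment_visible_offset
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)
    np.clip(values, 0.0, 1.0, out=values)
    values[truth.mask] = 0.0
    return SpectralImage(values, date=truth.date, mask=truth.mask.copy(),
                         header=config.header(bands=m))


class SamplingError(ValidationError):
    """A class has fewer pixels than the requested sample size."""


def sample_rois(truth: ClassMap, image: SpectralImage, per_class_n: int,
                seed: int) -> TrainingSet:
    """Uniform per-class sample of labeled pixels, without replacement."""
    if per_class_n < 1:
        raise ConfigurationError("per_class_n must be >= 1")
    if truth.shape != image.shape:
        raise_shape = f"truth {truth.shape} vs image {image.shape}"
        raise ConfigurationError(f"shape mismatch: {raise_shape}")
    rng = np.random.default_rng(seed)
    flat_labels = truth.labels.ravel()
    flat_values = image.values.reshape(-1, image.band_count)
    samples: dict[int, np.ndarray] = {}
    indices: dict[int, np.ndarray] = {}
    for code in CLASS_CODES:
        pool = np.flatnonzero(flat_labels == code)
        if pool.size == 0:
            continue
        if pool.size < per_class_n:
            raise SamplingError(
                f"class {CLASS_NAMES[code]!r} has only {pool.size} pixels, "
                f"cannot sample {per_class_n}")
        chosen = np.sort(rng.choice(pool, size=per_class_n, replace=False))
        samples[code] = flat_values[chosen]
        indices[code] = chosen
    return TrainingSet(samples=samples, indices=indices)


def simulate_pack(config: SimulationConfig) -> ScenePack:
    """Generate the full scene stack for a config (DEM, levels, truth, imagery)."""
    dem = make_dem(config)
    series = water_level_series(config)
    rng = config.rng("spectra")
    dates, levels, truths, images = [], [], [], []
    for date, level in series:
        truth = render_truth(dem, level, config)
        truth.date = date
        image = render_spectra(truth, config, rng=rng)
        dates.append(date)
        levels.append(level)
        truths.append(truth)
        images.append(image)
    return ScenePack(dem=dem, dates=dates, levels=levels, truths=truths,
                     images=images, config=config)
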