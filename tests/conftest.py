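import numpy as np
import pytest

from lakecover.grids import ClassMap, RasterHeader, SpectralImage
from lakecover.synth import SimulationConfig, sample_rois, simulate_pack


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(grid_rows=32, grid_cols=32, n_years=3,
                            scenes_per_year=4, seed=11)


@pytest.fixture(scope="session")
def small_pack(small_config):
    return simulate_pack(small_config)


@pytest.fixture(scope="session")
def noiseless_pack():
    cfg = SimulationConfig(grid_rows=24, grid_cols=24, n_years=2,
                           scenes_per_year=4, noise_sd=0.0,
                           interannual_sd=0.0, seed=5)
    return simulate_pack(cfg)


@pytest.fixture(scope="session")
def trained_scene(small_pack):
    """(truth, image, training set) for the first scene of the small pack."""
    truth, image = small_pack.truths[0], small_pack.images[0]
    train = sample_rois(truth, image, per_class_n=40, seed=3)
    return truth, image, train


def make_class_map(labels, pixel_size=30.0, date="2020-01-15") -> ClassMap:
    labels = np.asarray(labels, dtype=np.uint8)
    rows, cols = labels.shape
    header = RasterHeader(rows=rows, cols=cols, bands=1, dtype="uint8",
                          transform=(pixel_size, 0, 0, 0, -pixel_size, 0))
    return ClassMap(labels, date=date, header=header)


def make_image(values, date="2020-01-15") -> SpectralImage:
    return SpectralImage(np.asarray(values, dtype=float), date=date)
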