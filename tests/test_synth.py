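import numpy as np
import pytest

from lakecover.grids import (
    CLASS_CODES,
    MUDFLAT,
    SAND,
    VEGETATION,
    WATER,
    ConfigurationError,
)
from lakecover.synth import (
    BAND_NIR,
    SamplingError,
    SimulationConfig,
    make_dem,
    render_spectra,
    render_truth,
    sample_rois,
    simulate_pack,
    water_level_series,
)


class TestConfig:
    def test_rejects_nonpositive_grid(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(grid_rows=0)

    def test_rejects_negative_noise(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(noise_sd=-0.1)

    def test_rejects_reflectance_outside_unit_interval(self):
        sig = dict(SimulationConfig().signature_table)
        sig[WATER] = (1.2, 0.1, 0.1, 0.1, 0.1, 0.1)
        with pytest.raises(ConfigurationError):
            SimulationConfig(signature_table=sig)

    def test_rejects_bad_spectral_ordering(self):
        sig = dict(SimulationConfig().signature_table)
        # water NIR above vegetation NIR violates the ordering constraint
        sig[WATER] = (0.06, 0.08, 0.06, 0.9, 0.01, 0.01)
        with pytest.raises(ConfigurationError):
            SimulationConfig(signature_table=sig)


class TestMakeDem:
    def test_deterministic_for_same_seed(self):
        a = make_dem(SimulationConfig(seed=4))
        b = make_dem(SimulationConfig(seed=4))
        np.testing.assert_array_equal(a.values, b.values)

    def test_seed_sensitivity(self):
        a = make_dem(SimulationConfig(seed=1))
        b = make_dem(SimulationConfig(seed=2))
        assert np.any(a.values != b.values)

    def test_pure_bowl_minimum_at_center(self):
        cfg = SimulationConfig(grid_rows=33, grid_cols=33,
                               dem_noise_amplitude=0.0)
        dem = make_dem(cfg)
        # bowl formula evaluates to exactly 0 at the center cell
        assert dem.values[16, 16] == 0.0
        assert dem.values.min() == dem.values[16, 16]

    def test_rejects_tiny_grid(self):
        with pytest.raises(ConfigurationError):
            make_dem(SimulationConfig(grid_rows=4, grid_cols=4))


class TestWaterLevelSeries:
    def test_degenerate_constant(self):
        cfg = SimulationConfig(water_level_amplitude=0.0, interannual_sd=0.0)
        levels = [lv for _, lv in water_level_series(cfg)]
        assert levels == [cfg.water_level_base] * len(levels)

    def test_length(self):
        cfg = SimulationConfig(n_years=5, scenes_per_year=3)
        assert len(water_level_series(cfg)) == 15

    @pytest.mark.parametrize("scenes_per_year", [1, 2, 4, 6, 12])
    def test_argmax_month_in_high_season(self, scenes_per_year):
        cfg = SimulationConfig(scenes_per_year=scenes_per_year, seed=9)
        series = water_level_series(cfg)
        by_year = {}
        for date, level in series:
            by_year.setdefault(date[:4], []).append((level, int(date[5:7])))
        for year, pairs in by_year.items():
            _, month = max(pairs)
            assert month in (6, 7, 8, 9)

    def test_monthly_sampling_spans_twice_amplitude(self):
        cfg = SimulationConfig(scenes_per_year=12, interannual_sd=0.0,
                               water_level_amplitude=1.7, n_years=1)
        levels = np.array([lv for _, lv in water_level_series(cfg)])
        assert levels.max() - levels.min() == pytest.approx(2 * 1.7)

    def test_dates_strictly_increasing(self):
        dates = [d for d, _ in water_level_series(SimulationConfig())]
        assert dates == sorted(dates) and len(set(dates)) == len(dates)


class TestRenderTruth:
    def test_full_submergence(self):
        cfg = SimulationConfig(seed=1)
        dem = make_dem(cfg)
        cmap = render_truth(dem, dem.values.max() + 1, cfg)
        assert np.all(cmap.labels == WATER)

    def test_full_exposure(self):
        cfg = SimulationConfig(seed=1)
        dem = make_dem(cfg)
        cmap = render_truth(dem, dem.values.min() - 1, cfg)
        assert not np.any(cmap.labels == WATER)

    def test_monotone_in_level(self):
        cfg = SimulationConfig(seed=2)
        dem = make_dem(cfg)
        prev_water, prev_veg = -1, None
        for level in np.linspace(dem.values.min(), dem.values.max(), 12):
            cmap = render_truth(dem, level, cfg)
            water = int(np.count_nonzero(cmap.labels == WATER))
            veg = int(np.count_nonzero(cmap.labels == VEGETATION))
            assert water >= prev_water
            prev_water = water
        # rising level eventually removes vegetation entirely
        assert veg == 0 or level >= dem.values.max()

    def test_partition(self, small_pack):
        for truth in small_pack.truths:
            counts = truth.class_counts()
            assert sum(counts.values()) == truth.labels.size


class TestRenderSpectra:
    def test_zero_noise_reproduces_signatures(self, noiseless_pack):
        cfg = noiseless_pack.config
        truth, image = noiseless_pack.truths[0], noiseless_pack.images[0]
        for code in CLASS_CODES:
            where = truth.labels == code
            if not where.any():
                continue
            expected = np.asarray(cfg.signature_table[code])
            np.testing.assert_allclose(
                image.values[where],
                np.broadcast_to(expected, image.values[where].shape))

    def test_water_nir_below_vegetation_nir(self, small_pack):
        truth, image = small_pack.truths[0], small_pack.images[0]
        nir = image.values[:, :, BAND_NIR]
        assert nir[truth.labels == WATER].mean() < nir[truth.labels == VEGETATION].mean()

    def test_sample_mean_near_signature(self):
        cfg = SimulationConfig(grid_rows=160, grid_cols=160, noise_sd=0.02,
                               seed=21)
        dem = make_dem(cfg)
        truth = render_truth(dem, np.quantile(dem.values, 0.6), cfg)
        image = render_spectra(truth, cfg, rng=np.random.default_rng(3))
        water = truth.labels == WATER
        n = int(water.sum())
        assert n >= 10_000
        sig = np.asarray(cfg.signature_table[WATER])
        sample_mean = image.values[water].mean(axis=0)
        # clipping at 0 inflates the two near-zero SWIR bands slightly;
        # the law-of-large-numbers bound applies to the interior bands
        interior = sig >= 3 * cfg.noise_sd
        tol = 3 * cfg.noise_sd / np.sqrt(n)
        assert np.all(np.abs(sample_mean[interior] - sig[interior]) < tol)

    def test_missing_signature_errors(self):
        cfg = SimulationConfig(seed=1)
        dem = make_dem(cfg)
        truth = render_truth(dem, cfg.water_level_base, cfg)
        cfg.signature_table.pop(SAND, None)
        if SAND in np.unique(truth.labels):
            with pytest.raises(ConfigurationError, match="sand"):
                render_spectra(truth, cfg)


class TestSampleRois:
    def test_exhaustive_sample_returns_class(self, small_pack):
        truth, image = small_pack.truths[0], small_pack.images[0]
        n_water = int(np.count_nonzero(truth.labels == WATER))
        train = sample_rois(truth, image, per_class_n=min(n_water, 30), seed=0)
        assert train.samples[WATER].shape[0] == min(n_water, 30)

    def test_deterministic(self, small_pack):
        truth, image = small_pack.truths[0], small_pack.images[0]
        a = sample_rois(truth, image, 20, seed=5)
        b = sample_rois(truth, image, 20, seed=5)
        for code in a.indices:
            np.testing.assert_array_equal(a.indices[code], b.indices[code])

    def test_oversampling_names_class(self, small_pack):
        truth, image = small_pack.truths[0], small_pack.images[0]
        with pytest.raises(SamplingError) as err:
            sample_rois(truth, image, per_class_n=10**6, seed=0)
        assert any(name in str(err.value)
                   for name in ("water", "vegetation", "mudflat", "sand"))


class TestScenePack:
    def test_water_frequency_matches_dem_oracle(self, noiseless_pack):
        pack = noiseless_pack
        dem = pack.dem.values
        counts = np.zeros(dem.shape, dtype=int)
        for level in pack.levels:
            counts += dem < level
        from_truth = np.zeros(dem.shape, dtype=int)
        for truth in pack.truths:
            from_truth += truth.labels == WATER
        np.testing.assert_array_equal(counts, from_truth)

    def test_downstream_accuracy(self, trained_scene):
        from lakecover.classify import confusion, fit_mlc, mlc_classify
        truth, image, train = trained_scene
        cmap = mlc_classify(image, fit_mlc(train))
        assert confusion(cmap, truth).overall_accuracy >= 0.95
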