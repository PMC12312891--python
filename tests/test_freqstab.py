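import numpy as np
import pytest

from lakecover.freqstab import (
    accumulate_frequency,
    annual_presence,
    binarize,
    classify_frequency,
    cv_map,
    frequency_share,
    modal_map,
    stability_classes,
    tercile_breaks,
    transfer_matrix,
)
from lakecover.grids import (
    ConfigurationError,
    MUDFLAT,
    SAND,
    ShapeError,
    VEGETATION,
    WATER,
    ValidationError,
)

from conftest import make_class_map


class TestBinarize:
    def test_saturation(self):
        m = make_class_map(np.full((4, 4), WATER))
        assert binarize(m, WATER).sum() == 16

    def test_absent_class_all_zero(self):
        m = make_class_map(np.full((4, 4), WATER))
        assert binarize(m, SAND).sum() == 0

    def test_partition(self, small_pack):
        truth = small_pack.truths[0]
        total = sum(binarize(truth, c) for c in (WATER, VEGETATION, MUDFLAT, SAND))
        assert np.all(total[~truth.mask] == 1)

    def test_nodata_marked(self):
        labels = np.array([[0, 1], [2, 0]], dtype=np.uint8)
        out = binarize(make_class_map(labels), WATER)
        assert out[0, 0] == -1 and out[1, 1] == -1


class TestAnnualPresence:
    def test_majority_two_of_three(self):
        grids = [np.array([[1]]), np.array([[1]]), np.array([[0]])]
        assert annual_presence(grids)[0, 0] == 1  # mean 2/3 >= 0.5

    def test_minority_one_of_four(self):
        grids = [np.array([[0]])] * 3 + [np.array([[1]])]
        assert annual_presence(grids)[0, 0] == 0  # mean 0.25 < 0.5

    def test_tie_counts_as_present(self):
        grids = [np.array([[1]]), np.array([[0]])]
        assert annual_presence(grids)[0, 0] == 1

    def test_single_scene_identity(self):
        grid = np.array([[1, 0], [0, 1]], dtype=np.int8)
        np.testing.assert_array_equal(annual_presence([grid]), grid)

    def test_any_rule(self):
        grids = [np.array([[0]])] * 3 + [np.array([[1]])]
        assert annual_presence(grids, rule="any")[0, 0] == 1

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            annual_presence([np.zeros((2, 2)), np.zeros((3, 3))])


class TestAccumulateFrequency:
    def test_always_present_saturates(self):
        grids = [np.ones((3, 3), dtype=np.int8)] * 9
        freq = accumulate_frequency(grids)
        assert np.all(freq.counts == 9) and freq.n_years == 9

    def test_never_present_zero_then_null_bin(self):
        grids = [np.zeros((2, 2), dtype=np.int8)] * 9
        freq = accumulate_frequency(grids)
        fmap = classify_frequency(freq)
        assert np.all(freq.counts == 0)
        assert np.all(fmap.categories == 0)  # null, not a bin

    def test_matches_dem_level_oracle(self, noiseless_pack):
        pack = noiseless_pack
        by_year: dict[str, list] = {}
        for date, _, truth, _ in pack.scenes():
            by_year.setdefault(date[:4], []).append(binarize(truth, WATER))
        years = sorted(by_year)
        annual = [annual_presence(by_year[y]) for y in years]
        freq = accumulate_frequency(annual)
        # oracle: recompute presence from DEM and levels directly
        dem = pack.dem.values
        oracle = np.zeros(dem.shape, dtype=int)
        for y in years:
            flooded = [dem < lvl for d, lvl in zip(pack.dates, pack.levels)
                       if d.startswith(y)]
            oracle += np.mean(flooded, axis=0) >= 0.5
        np.testing.assert_array_equal(freq.counts, oracle)


class TestClassifyFrequency:
    def make_freq(self, counts):
        return accumulate_frequency(
            [np.asarray(counts, dtype=np.int8) * 0 + (np.asarray(counts) > i)
             for i in range(9)])

    def test_bin_edges_half_open(self):
        freq = self.make_freq(np.array([[3, 4], [5, 8]]))
        fmap = classify_frequency(freq, scheme="water")
        assert fmap.categories[0, 0] == 1  # 3 in (0, 3]
        assert fmap.categories[0, 1] == 2  # 4 in (3, 5]
        assert fmap.categories[1, 0] == 2  # 5 in (3, 5]
        assert fmap.categories[1, 1] == 4  # 8 in (7, 9]

    def test_water_vs_vegetation_names(self):
        freq = self.make_freq(np.array([[4]]))
        water = classify_frequency(freq, scheme="water")
        veg = classify_frequency(freq, scheme="vegetation")
        assert water.names[water.categories[0, 0] - 1] == "medium"
        assert veg.names[veg.categories[0, 0] - 1] == "relatively low"

    def test_count_above_top_edge_rejected(self):
        grids = [np.ones((1, 1), dtype=np.int8)] * 10
        freq = accumulate_frequency(grids)
        with pytest.raises(ValidationError):
            classify_frequency(freq, edges=(0, 3, 5, 7, 9))


class TestFrequencyShare:
    def test_uniform_high(self):
        grids = [np.ones((4, 4), dtype=np.int8)] * 9
        fmap = classify_frequency(accumulate_frequency(grids))
        shares = frequency_share(fmap)
        assert shares["shares"]["high"] == 1.0

    def test_shares_sum_to_one(self, small_pack):
        by_year: dict[str, list] = {}
        for date, _, truth, _ in small_pack.scenes():
            by_year.setdefault(date[:4], []).append(binarize(truth, WATER))
        annual = [annual_presence(v) for v in by_year.values()]
        freq = accumulate_frequency(annual)
        fmap = classify_frequency(freq, edges=(0, 1, 2, 3))
        shares = frequency_share(fmap)["shares"]
        assert sum(shares.values()) == pytest.approx(1.0)

    def test_all_null_errors(self):
        grids = [np.zeros((2, 2), dtype=np.int8)] * 9
        fmap = classify_frequency(accumulate_frequency(grids))
        with pytest.raises(ValidationError):
            frequency_share(fmap)


class TestCvMap:
    def test_constant_presence_zero_cv(self):
        grids = [np.ones((2, 2), dtype=np.int8)] * 5
        cv = cv_map(grids)
        np.testing.assert_allclose(cv.cv, 0.0)

    def test_hand_worked_half_presence(self):
        # F = {1, 1, 0, 0}: mean 0.5, population sd 0.5 -> CV = 100%
        grids = [np.ones((1, 1), dtype=np.int8)] * 2 + \
                [np.zeros((1, 1), dtype=np.int8)] * 2
        cv = cv_map(grids)
        assert cv.cv[0, 0] == pytest.approx(100.0)

    def test_never_present_null(self):
        grids = [np.zeros((2, 2), dtype=np.int8)] * 4
        cv = cv_map(grids)
        assert np.all(np.isnan(cv.cv))

    def test_year_order_invariance(self, small_pack):
        by_year: dict[str, list] = {}
        for date, _, truth, _ in small_pack.scenes():
            by_year.setdefault(date[:4], []).append(binarize(truth, WATER))
        annual = [annual_presence(v) for v in by_year.values()]
        a = cv_map(annual)
        b = cv_map(annual[::-1])
        np.testing.assert_allclose(a.cv, b.cv, equal_nan=True)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        grids = [rng.integers(0, 2, (5, 5)).astype(np.int8) for _ in range(6)]
        cv = cv_map(grids)
        stack = np.stack(grids).astype(float)
        for i in range(5):
            for j in range(5):
                f = stack[:, i, j]
                if f.mean() == 0:
                    assert np.isnan(cv.cv[i, j])
                else:
                    expect = np.sqrt(np.sum((f - f.mean()) ** 2) / len(f)) \
                        / f.mean() * 100.0
                    assert cv.cv[i, j] == pytest.approx(expect)


class TestStability:
    def test_zero_cv_everywhere_high(self):
        grids = [np.ones((3, 3), dtype=np.int8)] * 4
        stab = stability_classes(cv_map(grids), breaks=(10.0, 50.0))
        assert np.all(stab.categories == 1)
        assert stab.names[0] == "high"

    def test_two_region_split(self):
        cv = cv_map([np.ones((1, 2), dtype=np.int8),
                     np.array([[1, 0]], dtype=np.int8)])
        # pixel 0: CV 0; pixel 1: F = {1, 0} -> CV 100
        stab = stability_classes(cv, breaks=(50.0,), names=("stable", "unstable"))
        assert stab.categories[0, 0] == 1 and stab.categories[0, 1] == 2

    def test_nonmonotone_breaks_rejected(self):
        grids = [np.ones((2, 2), dtype=np.int8)] * 3
        with pytest.raises(ConfigurationError):
            stability_classes(cv_map(grids), breaks=(50.0, 10.0))

    def test_shares_partition(self, small_pack):
        by_year: dict[str, list] = {}
        for date, _, truth, _ in small_pack.scenes():
            by_year.setdefault(date[:4], []).append(binarize(truth, WATER))
        annual = [annual_presence(v) for v in by_year.values()]
        cv = cv_map(annual)
        stab = stability_classes(cv, breaks=tercile_breaks(cv))
        assert sum(stab.shares().values()) == pytest.approx(1.0)

    def test_basin_center_stable_shore_unstable(self, small_pack):
        dem = small_pack.dem.values
        by_year: dict[str, list] = {}
        for date, _, truth, _ in small_pack.scenes():
            by_year.setdefault(date[:4], []).append(binarize(truth, WATER))
        annual = [annual_presence(v) for v in by_year.values()]
        cv = cv_map(annual)
        deep = dem < min(small_pack.levels)  # always flooded
        assert deep.any()
        np.testing.assert_allclose(cv.cv[deep], 0.0)
        finite = np.isfinite(cv.cv)
        shore = finite & ~deep
        if shore.any():
            assert np.nanmax(cv.cv[shore]) >= np.nanmax(cv.cv[deep])


class TestModalMap:
    def test_single_map_identity(self):
        m = make_class_map(np.array([[1, 2], [3, 4]]))
        np.testing.assert_array_equal(modal_map([m]).labels, m.labels)

    def test_majority(self):
        maps = [make_class_map(np.array([[WATER]])),
                make_class_map(np.array([[WATER]])),
                make_class_map(np.array([[VEGETATION]]))]
        assert modal_map(maps).labels[0, 0] == WATER

    def test_tie_breaks_to_lowest_code(self):
        maps = [make_class_map(np.array([[WATER]])),
                make_class_map(np.array([[VEGETATION]]))]
        assert modal_map(maps).labels[0, 0] == WATER

    def test_all_nodata_stays_nodata(self):
        maps = [make_class_map(np.array([[0]])), make_class_map(np.array([[0]]))]
        assert modal_map(maps).labels[0, 0] == 0


class TestTransferMatrix:
    def test_identity_diagonal(self):
        m = make_class_map(np.array([[1, 2], [3, 4]]))
        tm = transfer_matrix(m, m)
        assert np.all(tm.areas == np.diag(np.diag(tm.areas)))
        np.testing.assert_allclose(tm.decreasing, 0.0)
        np.testing.assert_allclose(tm.increasing, 0.0)

    def test_hand_worked_2x2_toy(self):
        origin = make_class_map(np.array([[1, 1], [2, 2]]), pixel_size=30.0)
        dest = make_class_map(np.array([[1, 2], [2, 2]]), pixel_size=30.0)
        tm = transfer_matrix(origin, dest)
        i_w, i_v = tm.labels.index(WATER), tm.labels.index(VEGETATION)
        assert tm.areas[i_w, i_v] == pytest.approx(0.0009)
        assert tm.decreasing[i_w] == pytest.approx(0.0009)

    def test_total_area_conserved(self, small_pack):
        a, b = small_pack.truths[0], small_pack.truths[-1]
        tm = transfer_matrix(a, b)
        n_valid = np.count_nonzero((a.labels != 0) & (b.labels != 0))
        assert tm.grand_total == pytest.approx(n_valid * a.header.pixel_area_km2)

    def test_marginals_reproduce_class_areas(self, small_pack):
        a, b = small_pack.truths[0], small_pack.truths[-1]
        tm = transfer_matrix(a, b)
        px = a.header.pixel_area_km2
        for i, code in enumerate(tm.labels):
            assert tm.row_totals[i] == pytest.approx(
                np.count_nonzero(a.labels == code) * px)
            assert tm.col_totals[i] == pytest.approx(
                np.count_nonzero(b.labels == code) * px)

    def test_frame_layout(self):
        m = make_class_map(np.array([[1, 2], [3, 4]]))
        df = transfer_matrix(m, m).to_frame()
        assert list(df.columns[-2:]) == ["Total", "Decreasing"]
        assert list(df.index[-2:]) == ["Total", "Increasing"]

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            transfer_matrix(make_class_map(np.ones((2, 2), dtype=np.uint8)),
                            make_class_map(np.ones((3, 3), dtype=np.uint8)))
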