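import numpy as np
import pandas as pd
import pytest

from cisa import (
    CellTable,
    LabelMask,
    MarkerImage,
    RegionMasks,
    assign_region,
    call_loaded_macrophages,
    classify_cells,
    multi_otsu,
    preprocess_channel,
    region_mask_from_channel,
    tumor_stroma,
    two_means_split,
)
from cisa.annotation import _fill_small_holes, _remove_small_components
from cisa.model import ThresholdModel
from oracles import (
    exhaustive_multiotsu,
    exhaustive_two_means,
    gaussian_impulse_response,
    upper_quartile_mean_sorted,
)


class TestPreprocessChannel:
    def test_constant_image_maps_to_constant_log(self):
        img = MarkerImage({"c": np.full((20, 20), 7.0)}, 1.0)
        out = preprocess_channel(img, "c")
        np.testing.assert_allclose(out, 3.0, atol=1e-9)

    def test_zero_image_stays_zero(self):
        img = MarkerImage({"c": np.zeros((10, 10))}, 1.0)
        np.testing.assert_array_equal(preprocess_channel(img, "c"), 0.0)

    def test_impulse_matches_discrete_gaussian_convolution(self):
        raw = np.zeros((21, 21))
        raw[10, 10] = 100.0
        img = MarkerImage({"c": raw}, 1.0)
        out = preprocess_channel(img, "c")
        want = np.log2(100.0 * gaussian_impulse_response((21, 21), (10, 10)) + 1.0)
        np.testing.assert_allclose(out, want, atol=1e-6)


class TestMultiOtsu:
    def test_four_spikes_thresholds_between_modes(self):
        vals = np.repeat([0.0, 10.0, 100.0, 200.0], [50, 40, 30, 20])
        m = multi_otsu(vals, 4)
        assert 0 < m.thresholds[0] < 10
        assert 10 < m.thresholds[1] < 100
        assert 100 < m.thresholds[2] < 200
        np.testing.assert_allclose(m.class_means, [0, 10, 100, 200])

    def test_too_few_distinct_values_is_error(self):
        with pytest.raises(ValueError, match="distinct"):
            multi_otsu(np.repeat([1.0, 5.0], 10), 4)

    def test_random_8bit_histograms_match_exhaustive_search(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            levels = np.sort(rng.choice(256, size=24, replace=False))
            counts = rng.integers(1, 50, size=24)
            values = np.repeat(levels.astype(float), counts)
            m = multi_otsu(values, 4)
            _, optimal = exhaustive_multiotsu(levels.tolist(), counts.tolist(), 4)
            assert tuple(float(t) for t in m.thresholds) in {
                tuple(float(t) for t in cand) for cand in optimal
            }

    def test_class_means_strictly_increasing(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [rng.normal(mu, 1.0, 200) for mu in (0, 5, 12, 30)]
        )
        m = multi_otsu(vals, 4)
        assert np.all(np.diff(m.class_means) > 0)


class TestRegionMaskCleanup:
    def test_hole_boundary_2499_filled_2500_kept(self):
        base = np.ones((120, 120), bool)
        base[10:60, 10:60] = False  # 2500 px hole: kept
        out = _fill_small_holes(base, 2500)
        assert not out[30, 30]
        base2 = np.ones((120, 120), bool)
        base2[10:60, 10:59] = False  # 2450 px
        base2[10, 59] = False  # 2451... make exactly 2499: 49*51=2499
        base3 = np.ones((120, 120), bool)
        base3[10:59, 10:61] = False  # 49*51 = 2499 px hole: filled
        out3 = _fill_small_holes(base3, 2500)
        assert out3.all()

    def test_object_boundary_2499_removed_2500_kept(self):
        img = np.zeros((120, 120), bool)
        img[10:59, 10:61] = True  # 2499
        assert not _remove_small_components(img, 2500).any()
        img2 = np.zeros((120, 120), bool)
        img2[10:60, 10:60] = True  # 2500
        assert _remove_small_components(img2, 2500).sum() == 2500

    def test_bright_blob_recovered_as_single_component(self):
        rng = np.random.default_rng(2)
        raw = np.full((200, 200), 1.0)
        raw[40:160, 40:160] = 300.0
        raw *= 1 + 0.05 * rng.normal(size=raw.shape)
        img = MarkerImage({"c": np.clip(raw, 0, None)}, 1.0)
        smoothed = preprocess_channel(img, "c")
        mask = region_mask_from_channel(smoothed)
        from scipy import ndimage

        lbl, n = ndimage.label(mask)
        assert n == 1
        truth = np.zeros((200, 200), bool)
        truth[40:160, 40:160] = True
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou > 0.9

    def test_blob_under_size_filter_yields_empty_mask(self):
        raw = np.full((200, 200), 1.0)
        raw[10:50, 10:50] = 300.0  # 1600 px: below 2500 even after blur halo
        img = MarkerImage({"c": raw}, 1.0)
        smoothed = preprocess_channel(img, "c")
        with pytest.warns(UserWarning, match="empty"):
            mask = region_mask_from_channel(smoothed)
        assert not mask.any()

    def test_closing_and_fill_match_stepwise_morphology(self):
        """Two blobs 6 px apart bridge under a 10x10 closing; the enclosed
        gap is then filled as a small hole."""
        from skimage.morphology import closing

        binary = np.zeros((200, 260), bool)
        binary[40:160, 40:120] = True
        binary[40:160, 126:206] = True
        closed = closing(binary, footprint=np.ones((10, 10), bool))
        want = _fill_small_holes(closed, 2500)
        raw = np.where(binary, 300.0, 1.0)
        smoothed = preprocess_channel(MarkerImage({"c": raw}, 1.0), "c")
        got = region_mask_from_channel(smoothed)
        # blur shifts the boundary by at most a pixel or two
        assert (got ^ want).sum() / want.sum() < 0.05
        assert got[100, 122]  # the gap column is closed and filled


class TestTumorStroma:
    def test_disjoint_masks_unchanged(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:5], b[6:] = True, True
        out = tumor_stroma(a, b)
        np.testing.assert_array_equal(out.tumor, a)
        np.testing.assert_array_equal(out.stroma, b)

    def test_identical_masks_empty_stroma(self):
        a = np.ones((5, 5), bool)
        out = tumor_stroma(a, a.copy())
        assert not out.stroma.any()

    def test_random_masks_boolean_algebra(self):
        rng = np.random.default_rng(3)
        a = rng.random((30, 30)) < 0.4
        b = rng.random((30, 30)) < 0.4
        out = tumor_stroma(a, b)
        for r in range(30):
            for c in range(30):
                assert out.stroma[r, c] == (b[r, c] and not a[r, c])
        assert not (out.tumor & out.stroma).any()

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            tumor_stroma(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestAssignRegion:
    def _masks(self):
        tumor = np.zeros((50, 50), bool)
        tumor[:25, :25] = True
        stroma = np.zeros((50, 50), bool)
        stroma[30:, 30:] = True
        return RegionMasks(tumor=tumor, stroma=stroma)

    def _table(self, xy):
        df = pd.DataFrame(
            {
                "cell_id": np.arange(1, len(xy) + 1),
                "x_um": [p[0] for p in xy],
                "y_um": [p[1] for p in xy],
                "types": [frozenset({"T-cell"})] * len(xy),
            }
        )
        return CellTable(df)

    def test_centroid_rules(self):
        table = assign_region(
            self._table([(10.0, 10.0), (40.0, 40.0), (10.0, 45.0)]),
            self._masks(),
            pixel_size_um=1.0,
        )
        assert table.df["region"].tolist() == ["intratumor", "stroma", "none"]

    def test_random_cells_match_mask_lookup(self):
        rng = np.random.default_rng(4)
        xy = [(rng.uniform(0, 49), rng.uniform(0, 49)) for _ in range(100)]
        masks = self._masks()
        table = assign_region(self._table(xy), masks, pixel_size_um=1.0)
        for (x, y), region in zip(xy, table.df["region"]):
            r, c = int(y), int(x)
            want = (
                "intratumor"
                if masks.tumor[r, c]
                else ("stroma" if masks.stroma[r, c] else "none")
            )
            assert region == want


class TestClassifyCells:
    def test_spec_like_example_split(self):
        t, pos = two_means_split(np.array([1.0, 1.0, 2.0, 10.0, 11.0]))
        assert t == 10.5
        np.testing.assert_array_equal(pos, [False, False, False, False, True])

    def test_single_outlier(self):
        vals = np.array([0.0] * 9 + [100.0])
        t, pos = two_means_split(vals)
        assert t == 100.0 and pos.sum() == 1

    def test_two_values(self):
        t, pos = two_means_split(np.array([0.0, 10.0]))
        assert t == 10.0
        np.testing.assert_array_equal(pos, [False, True])

    def test_all_identical_warns_all_negative(self):
        with pytest.warns(UserWarning, match="identical"):
            t, pos = two_means_split(np.ones(5))
        assert not pos.any()

    def test_random_values_match_exhaustive_split_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            vals = rng.normal(0, 3, size=rng.integers(5, 40))
            t_got, pos_got = two_means_split(vals)
            t_want, pos_want = exhaustive_two_means(vals)
            assert t_got == pytest.approx(t_want, abs=1e-10)
            np.testing.assert_array_equal(pos_got, pos_want)

    def test_classify_cells_applies_log_transform(self):
        df = pd.DataFrame(
            {
                "cell_id": [1, 2, 3, 4],
                "x_um": [0.0] * 4,
                "y_um": [0.0] * 4,
                "types": [frozenset({"cell"})] * 4,
                "mean_CD14": [0.0, 1.0, 30.0, 40.0],
            }
        )
        pos, model = classify_cells(CellTable(df), "CD14")
        logs = np.log2(np.array([0.0, 1.0, 30.0, 40.0]) + 1)
        t_want, pos_want = exhaustive_two_means(logs)
        assert model.thresholds[0] == pytest.approx(t_want)
        np.testing.assert_array_equal(pos, pos_want)


class TestLoadedMacrophages:
    def _setup(self, cyto_values, threshold_log):
        """One 5x5 macrophage; cytoplasm is the 3x3 interior (9 px)."""
        labels = np.zeros((9, 9), int)
        labels[2:7, 2:7] = 1
        chan = np.zeros((9, 9))
        vals = np.asarray(cyto_values, float).reshape(3, 3)
        chan[3:6, 3:6] = vals
        img = MarkerImage({"Mel": chan}, 1.0)
        df = pd.DataFrame(
            {
                "cell_id": [1],
                "x_um": [4.0],
                "y_um": [4.0],
                "types": [frozenset({"macrophage"})],
            }
        )
        model = ThresholdModel(
            channel="Mel", thresholds=np.array([threshold_log]),
            class_means=np.array([0.0, threshold_log + 1]),
        )
        return img, LabelMask(labels), CellTable(df), model

    def test_zero_cytoplasm_unloaded(self):
        img, mask, table, model = self._setup(np.zeros(9), threshold_log=0.5)
        out = call_loaded_macrophages(img, mask, table, "Mel", model)
        assert out.df["loaded"].iloc[0] is False

    def test_two_level_cytoplasm_upper_tail_mean(self):
        # 9 cytoplasm px: five 0s and four 4s -> q75 = 4, statistic 4
        vals = [0, 0, 0, 0, 0, 4, 4, 4, 4]
        img, mask, table, model = self._setup(vals, threshold_log=np.log2(5.0))
        out = call_loaded_macrophages(img, mask, table, "Mel", model)
        assert out.df["loaded"].iloc[0] is True  # log2(4+1) == threshold

    def test_random_cytoplasm_matches_sort_and_average(self):
        rng = np.random.default_rng(6)
        vals = rng.random(9) * 10
        stat = upper_quartile_mean_sorted(vals)
        img, mask, table, model = self._setup(vals, threshold_log=np.log2(stat + 1))
        out = call_loaded_macrophages(img, mask, table, "Mel", model)
        assert out.df["loaded"].iloc[0] is True
        img2, mask2, table2, model2 = self._setup(
            vals, threshold_log=np.log2(stat + 1) + 1e-6
        )
        out2 = call_loaded_macrophages(img2, mask2, table2, "Mel", model2)
        assert out2.df["loaded"].iloc[0] is False

    def test_tiny_cell_without_cytoplasm_flag_missing(self):
        labels = np.zeros((5, 5), int)
        labels[2, 2] = 1  # all membrane, no cytoplasm
        img = MarkerImage({"Mel": np.ones((5, 5))}, 1.0)
        df = pd.DataFrame(
            {
                "cell_id": [1],
                "x_um": [2.0],
                "y_um": [2.0],
                "types": [frozenset({"macrophage"})],
            }
        )
        model = ThresholdModel(
            channel="Mel", thresholds=np.array([1.0]), class_means=np.array([0, 2.0])
        )
        out = call_loaded_macrophages(img, LabelMask(labels), CellTable(df), "Mel", model)
        assert out.df["loaded"].iloc[0] is None

    def test_non_macrophages_untouched(self):
        img, mask, table, model = self._setup(np.ones(9), threshold_log=0.1)
        table.df["types"] = [frozenset({"T-cell"})]
        out = call_loaded_macrophages(img, mask, table, "Mel", model)
        assert out.df["loaded"].iloc[0] is None
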