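import numpy as np
import pytest
import shapely

from ecotone import (
    CovariateStack,
    Grid,
    GridGeometry,
    PairSpec,
    VegetationOccurrence,
    aggregate_mean,
    assert_aligned,
    extract_labeled_pixels,
    rasterize_occurrences,
)
from ecotone.grid_model import AlignmentError, UnusablePairError


class TestAssertAligned:
    def test_identical_geometry_returns_same_stack(self, gradient_stack):
        assert assert_aligned(gradient_stack) is gradient_stack

    def test_single_layer_is_trivially_aligned(self, small_geometry):
        stack = CovariateStack({"only": Grid(np.zeros((10, 10)), small_geometry)})
        assert assert_aligned(stack) is stack

    def test_shape_mismatch_names_offending_layer(self, small_geometry):
        other = GridGeometry(0.0, 10.0, 1.0, 10, 11, "test")
        with pytest.raises(AlignmentError, match="bad"):
            CovariateStack({
                "ok": Grid(np.zeros((10, 10)), small_geometry),
                "bad": Grid(np.zeros((10, 11)), other),
            })

    def test_crs_tag_mismatch_is_an_error(self, small_geometry):
        other = GridGeometry(0.0, 10.0, 1.0, 10, 10, "other-crs")
        with pytest.raises(AlignmentError):
            CovariateStack({
                "a": Grid(np.zeros((10, 10)), small_geometry),
                "b": Grid(np.zeros((10, 10)), other),
            })


class TestAggregateMean:
    def test_constant_grid_stays_constant(self):
        g = Grid.from_array(np.full((9, 9), 7.0))
        out = aggregate_mean(g, 3)
        assert out.values.shape == (3, 3)
        assert np.allclose(out.values, 7.0)
        assert out.geometry.cell_size == 3.0

    def test_hand_computed_block_mean(self):
        out = aggregate_mean(Grid.from_array([[1.0, 2.0], [3.0, 4.0]]), 2)
        assert out.values.shape == (1, 1)
        assert out.values[0, 0] == pytest.approx(2.5)

    def test_masked_cell_excluded_from_block_mean(self):
        mask = np.array([[False, True], [False, False]])
        g = Grid.from_array([[1.0, 99.0], [3.0, 4.0]], nodata_mask=mask)
        out = aggregate_mean(g, 2)
        assert out.values[0, 0] == pytest.approx(8.0 / 3.0)
        assert not out.nodata_mask[0, 0]

    def test_fully_masked_block_is_masked(self):
        g = Grid.from_array(np.ones((2, 2)), nodata_mask=np.ones((2, 2), bool))
        assert aggregate_mean(g, 2).nodata_mask[0, 0]

    def test_factor_one_is_identity(self):
        vals = np.arange(12, dtype=float).reshape(3, 4)
        mask = vals > 7
        g = Grid.from_array(vals, nodata_mask=mask)
        out = aggregate_mean(g, 1)
        assert np.array_equal(out.values, vals)
        assert np.array_equal(out.nodata_mask, mask)

    def test_global_mean_conserved_on_divisible_unmasked_grid(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(12, 18))
        out = aggregate_mean(Grid.from_array(vals), 3)
        assert out.values.mean() == pytest.approx(vals.mean(), abs=1e-12)

    def test_partial_edge_blocks_average_existing_cells(self):
        vals = np.arange(6, dtype=float).reshape(2, 3)  # 3 cols, factor 2
        out = aggregate_mean(Grid.from_array(vals), 2)
        assert out.values.shape == (1, 2)
        assert out.values[0, 1] == pytest.approx((2 + 5) / 2)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            aggregate_mean(Grid.from_array(np.ones((2, 2))), 0)


class TestRasterizeOccurrences:
    def test_single_class_coverage_is_unusable(self, small_geometry, pair):
        poly = shapely.box(-1, -1, 11, 11)
        with pytest.raises(UnusablePairError):
            rasterize_occurrences(
                [(poly, pair.subtropical_name)], small_geometry, pair
            )

    def test_polygon_covering_lower_rows_labels_their_centres(
        self, small_geometry, pair
    ):
        # polygon spans y < 9: pixel centres at y = 0.5 .. 8.5 (rows 1-9)
        poly = shapely.box(-1, -1, 11, 9)
        occ = rasterize_occurrences(
            [
                (poly, pair.subtropical_name),
                (shapely.Point(0.5, 9.5), pair.temperate_name),
            ],
            small_geometry,
            pair,
        )
        assert (occ.labels[1:] == 0).all()
        assert occ.labels[0, 0] == 1
        assert (occ.labels[0, 1:] == -1).all()

    def test_zero_features_is_an_error(self, small_geometry, pair):
        with pytest.raises(UnusablePairError):
            rasterize_occurrences([], small_geometry, pair)

    def test_disjoint_squares_give_exact_pixel_counts(self, small_geometry, pair):
        # 3x3-cell squares snapped to cell edges: 9 pixel centres each
        sub = shapely.box(0.0, 0.0, 3.0, 3.0)       # SW corner
        temp = shapely.box(6.0, 6.0, 9.0, 9.0)      # NE-ish
        occ = rasterize_occurrences(
            [(sub, pair.subtropical_name), (temp, pair.temperate_name)],
            small_geometry,
            pair,
        )
        assert (occ.labels == 0).sum() == 9
        assert (occ.labels == 1).sum() == 9
        assert (occ.labels == -1).sum() == 82

    def test_both_classes_on_one_pixel_excluded(self, small_geometry, pair):
        both = shapely.box(0, 0, 3, 3)
        extra_sub = shapely.box(5, 5, 6, 6)
        extra_temp = shapely.box(8, 8, 9, 9)
        occ = rasterize_occurrences(
            [
                (both, pair.subtropical_name),
                (both, pair.temperate_name),
                (extra_sub, pair.subtropical_name),
                (extra_temp, pair.temperate_name),
            ],
            small_geometry,
            pair,
        )
        # the 9 doubly-claimed pixels are -1; one of each class survives
        assert (occ.labels == 0).sum() == 1
        assert (occ.labels == 1).sum() == 1

    def test_point_features_label_containing_pixel(self, small_geometry, pair):
        occ = rasterize_occurrences(
            [
                (shapely.Point(2.5, 7.5), pair.subtropical_name),
                (shapely.Point(7.5, 2.5), pair.temperate_name),
            ],
            small_geometry,
            pair,
        )
        assert occ.labels[2, 2] == 0   # y=7.5 -> row 2
        assert occ.labels[7, 7] == 1
        assert (occ.labels == -1).sum() == 98

    def test_idempotent_on_own_geometry(self, small_geometry, pair):
        feats = [
            (shapely.box(0, 0, 3, 3), pair.subtropical_name),
            (shapely.box(6, 6, 9, 9), pair.temperate_name),
        ]
        once = rasterize_occurrences(feats, small_geometry, pair)
        twice = rasterize_occurrences(feats, once.geometry, pair)
        assert np.array_equal(once.labels, twice.labels)


class TestExtractLabeledPixels:
    def test_row_per_labeled_pixel(self, gradient_stack, split_occurrence):
        feats, labels, idx = extract_labeled_pixels(
            gradient_stack, split_occurrence, ["grad", "flat"]
        )
        assert feats.shape == (100, 2)
        assert set(labels) == {0, 1}
        assert np.array_equal(idx, np.arange(100))

    def test_masked_pixel_excluded(self, small_geometry, pair):
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True
        stack = CovariateStack({"v": Grid(np.ones((10, 10)), small_geometry, mask)})
        labels = np.full((10, 10), -1)
        labels[0, :2] = 1
        labels[1, :2] = 0
        occ = VegetationOccurrence(labels, pair, small_geometry)
        feats, lab, idx = extract_labeled_pixels(stack, occ, ["v"])
        assert feats.shape == (3, 1)
        assert np.array_equal(idx, [1, 10, 11])

    def test_row_count_identity(self, small_geometry, pair):
        rng = np.random.default_rng(0)
        mask = rng.random((10, 10)) < 0.2
        stack = CovariateStack(
            {"v": Grid(rng.normal(size=(10, 10)), small_geometry, mask)}
        )
        labels = rng.integers(-1, 2, size=(10, 10))
        occ = VegetationOccurrence(labels, pair, small_geometry)
        feats, _, _ = extract_labeled_pixels(stack, occ, ["v"])
        expected = ((labels >= 0) & ~mask).sum()
        assert feats.shape[0] == expected

    def test_all_masked_raises(self, small_geometry, pair, split_occurrence):
        stack = CovariateStack(
            {"v": Grid(np.ones((10, 10)), small_geometry, np.ones((10, 10), bool))}
        )
        with pytest.raises(UnusablePairError):
            extract_labeled_pixels(stack, split_occurrence, ["v"])

    def test_unknown_variable_raises(self, gradient_stack, split_occurrence):
        with pytest.raises(KeyError):
            extract_labeled_pixels(gradient_stack, split_occurrence, ["nope"])
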