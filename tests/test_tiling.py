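"""Tile grid construction and the hot-spot / whole-slide Ki67 indices."""

import numpy as np
import pytest
import shapely

from ki67score.errors import ConfigurationError, InvalidInputError
from ki67score.imaging import NucleusDetection
from ki67score.tiling import (
    Tile,
    build_grid,
    count_per_tile,
    hot_spot_index,
    score_slide,
    whole_slide_index,
)


def det(x, y, label="negative"):
    return NucleusDetection(x, y, 12.0, 0.0, 0.0, label=label)


def make_tile(row, col, total, positive, side=100):
    return Tile(row, col, col * side, row * side, (col + 1) * side, (row + 1) * side,
                total_cells=total, positive_cells=positive)


class TestBuildGrid:
    def test_exact_3x3_partition(self):
        # 1500x1500 um at 1 um/px: side 500 px, 9 tiles
        assert len(build_grid(shapely.box(0, 0, 1500, 1500), mpp=1.0)) == 9

    def test_partial_column_included(self):
        # 1501 um wide: a 1-px sliver column still intersects -> 4x3 tiles
        assert len(build_grid(shapely.box(0, 0, 1501, 1500), mpp=1.0)) == 12

    def test_region_inside_single_tile(self):
        assert len(build_grid(shapely.box(10, 10, 400, 300), mpp=1.0)) == 1

    def test_tile_side_scales_with_mpp(self):
        tiles = build_grid(shapely.box(0, 0, 3000, 3000), mpp=2.0, tile_size_um=500)
        assert tiles[0].x1 - tiles[0].x0 == 250
        assert len(tiles) == 144

    def test_non_intersecting_tiles_dropped(self):
        # right triangle: the far corner tile's box lies beyond the hypotenuse
        region = shapely.Polygon([(0, 0), (900, 0), (0, 900)])
        tiles = build_grid(region, mpp=1.0)
        assert {(t.row, t.col) for t in tiles} == {(0, 0), (0, 1), (1, 0)}

    def test_degenerate_region_rejected(self):
        with pytest.raises(InvalidInputError):
            build_grid(shapely.box(0, 0, 0, 0), mpp=1.0)

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigurationError):
            build_grid(shapely.box(0, 0, 100, 100), mpp=1.0, tile_size_um=0)


class TestCountPerTile:
    def test_no_detections_leaves_percent_undefined(self, unit_square):
        tiles = count_per_tile([], build_grid(unit_square, 1.0), unit_square)
        assert all(t.total_cells == 0 and t.percent_positive is None for t in tiles)

    def test_single_tile_percent(self):
        region = shapely.box(0, 0, 400, 400)
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 400, size=(1000, 2))
        dets = [det(x, y, "positive" if i < 300 else "negative")
                for i, (x, y) in enumerate(pts)]
        (tile,) = count_per_tile(dets, build_grid(region, 1.0), region)
        assert tile.total_cells == 1000
        assert tile.percent_positive == pytest.approx(30.0)

    def test_centroids_outside_polygon_excluded(self):
        # triangle inside its bounding box: points in the box but outside
        # the polygon must not be counted
        tri = shapely.Polygon([(0, 0), (1000, 0), (0, 1000)])
        inside = det(100, 100)
        outside = det(900, 900)  # inside bbox, outside triangle
        boundary = det(500, 500)  # on the hypotenuse: counts as inside
        tiles = count_per_tile([inside, outside, boundary], build_grid(tri, 1.0), tri)
        assert sum(t.total_cells for t in tiles) == 2

    def test_partition_invariant(self, unit_square, rng):
        pts = rng.uniform(0, 1000, size=(500, 2))
        dets = [det(x, y, "positive" if rng.random() < 0.3 else "negative")
                for x, y in pts]
        tiles = count_per_tile(dets, build_grid(unit_square, 1.0), unit_square)
        assert sum(t.total_cells for t in tiles) == 500

    def test_unclassified_detections_rejected(self, unit_square):
        with pytest.raises(InvalidInputError):
            count_per_tile([NucleusDetection(5, 5, 12, 0, 0)],
                           build_grid(unit_square, 1.0), unit_square)


class TestHotSpotIndex:
    def test_mean_of_top_five(self):
        tiles = [make_tile(0, i, 600, int(600 * p / 100))
                 for i, p in enumerate([10, 20, 30, 40, 50, 60, 70])]
        value, n_used, fallback = hot_spot_index(tiles)
        assert value == pytest.approx(50.0)
        assert n_used == 5 and not fallback

    def test_fallback_averages_all_qualifying(self):
        tiles = [make_tile(0, i, 500, int(500 * p / 100)) for i, p in enumerate([10, 20, 30])]
        value, n_used, fallback = hot_spot_index(tiles)
        assert value == pytest.approx(20.0)
        assert n_used == 3 and fallback

    def test_identical_percentages_give_that_percent(self):
        tiles = [make_tile(0, i, 1000, 250) for i in range(8)]
        value, _, _ = hot_spot_index(tiles)
        assert value == pytest.approx(25.0)

    def test_under_min_cells_tiles_never_qualify(self):
        tiles = [make_tile(0, 0, 499, 499), make_tile(0, 1, 500, 100)]
        value, n_used, _ = hot_spot_index(tiles)
        assert value == pytest.approx(20.0)  # 100% tile was below min_cells
        assert n_used == 1

    def test_no_qualifying_tiles_is_undefined(self):
        value, n_used, fallback = hot_spot_index([make_tile(0, 0, 10, 5)])
        assert value is None and n_used == 0 and fallback

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigurationError):
            hot_spot_index([], k=0)
        with pytest.raises(ConfigurationError):
            hot_spot_index([], min_cells=-1)

    def test_dominance_over_qualifying_mean(self, rng):
        """Mean of the top-k can never fall below the mean over all
        qualifying tiles (and equals it when <= k tiles qualify)."""
        for _ in range(200):
            n = rng.integers(1, 40)
            tiles = [
                make_tile(int(i // 8), int(i % 8), int(rng.integers(0, 2000)), 0)
                for i in range(n)
            ]
            for t in tiles:
                t.positive_cells = int(rng.integers(0, t.total_cells + 1))
            value, _, _ = hot_spot_index(tiles, min_cells=500, k=5)
            qualifying = [t.percent_positive for t in tiles if t.total_cells >= 500]
            if not qualifying:
                assert value is None
            else:
                assert value >= np.mean(qualifying) - 1e-12
                assert 0.0 <= value <= 100.0


class TestWholeSlideIndex:
    def test_macro_mean_not_pooled(self):
        tiles = [make_tile(0, 0, 100, 0), make_tile(0, 1, 1000, 1000)]
        assert whole_slide_index(tiles) == pytest.approx(50.0)  # pooled would be ~90.9

    def test_simple_mean(self):
        tiles = [make_tile(0, i, 100, p) for i, p in enumerate([10, 20, 30, 40, 50, 60, 70])]
        assert whole_slide_index(tiles) == pytest.approx(40.0)

    def test_zero_cell_tiles_excluded(self):
        tiles = [make_tile(0, 0, 0, 0), make_tile(0, 1, 10, 5)]
        assert whole_slide_index(tiles) == pytest.approx(50.0)

    def test_undefined_when_no_cells(self):
        assert whole_slide_index([make_tile(0, 0, 0, 0)]) is None


class TestScoreSlide:
    def test_scale_invariance_of_indices(self):
        tiles = [make_tile(0, i, 600, int(600 * p / 100))
                 for i, p in enumerate([10, 30, 50])]
        doubled = [make_tile(0, i, 1200, int(1200 * p / 100))
                   for i, p in enumerate([10, 30, 50])]
        assert hot_spot_index(tiles)[0] == pytest.approx(hot_spot_index(doubled)[0])
        assert whole_slide_index(tiles) == pytest.approx(whole_slide_index(doubled))

    def test_empty_annotation_rejected(self, small_slide):
        image, _, _ = small_slide
        with pytest.raises(InvalidInputError):
            score_slide(image, shapely.Polygon())

    def test_hotspot_slide_has_hotspot_index_above_whole_slide(self, small_slide):
        image, _, region = small_slide
        score = score_slide(image, region, min_cells=150)
        assert score.hot_spot_index > score.whole_slide_index

    def test_deterministic_tile_table(self, small_slide):
        from ki67score.io import tiles_to_frame

        image, _, region = small_slide
        a = score_slide(image, region)
        b = score_slide(image, region)
        assert tiles_to_frame(a.tiles).to_csv() == tiles_to_frame(b.tiles).to_csv()
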