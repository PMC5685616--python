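"""Raster data model, ASCII I/O, cell conventions, and polygon membership."""

import math

import numpy as np
import pytest

from sdmshift.errors import AlignmentError, FormatError, GeometryError
from sdmshift.grid import (
    KM_PER_DEG,
    RasterGrid,
    distance_to_polygon_km,
    haversine_km,
    occurrences_to_cells,
    point_in_polygon,
    read_raster,
    write_raster,
)


def _winding_inside(x, y, poly):
    """Brute-force winding-number oracle (boundary treated separately)."""
    wn = 0
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if y1 <= y < y2 and (x2 - x1) * (y - y1) - (x - x1) * (y2 - y1) > 0:
            wn += 1
        elif y2 <= y < y1 and (x2 - x1) * (y - y1) - (x - x1) * (y2 - y1) < 0:
            wn -= 1
    return wn != 0


class TestRasterIO:
    def test_roundtrip_preserves_values_mask_transform(self, tmp_path, small_grid):
        small_grid.mask[1, 1] = True
        path = tmp_path / "g.asc"
        write_raster(small_grid, path)
        back = read_raster(path)
        assert np.allclose(back.values[~back.mask],
                           small_grid.values[~small_grid.mask], rtol=1e-7)
        assert np.array_equal(back.mask, small_grid.mask)
        assert back.origin_x == small_grid.origin_x
        assert back.origin_y == pytest.approx(small_grid.origin_y)
        assert back.cell_size == small_grid.cell_size

    def test_nodata_cells_are_masked(self, tmp_path):
        path = tmp_path / "n.asc"
        path.write_text(
            "NCOLS 3\nNROWS 2\nXLLCORNER 0\nYLLCORNER 0\nCELLSIZE 1\n"
            "NODATA_VALUE -9999\n1 -9999 3\n-9999 5 6\n"
        )
        grid = read_raster(path)
        assert grid.mask.sum() == 2
        assert grid.mask[0, 1] and grid.mask[1, 0]

    def test_geotiff_rejected(self, tmp_path):
        path = tmp_path / "x.tif"
        path.write_bytes(b"II*\x00")
        with pytest.raises(FormatError):
            read_raster(path)

    def test_garbage_rejected(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("not a raster at all\n")
        with pytest.raises(FormatError):
            read_raster(path)


class TestCellConventions:
    def test_cell_center(self, small_grid):
        x, y = small_grid.cell_center(0, 0)
        assert (float(x), float(y)) == (30.25, 30.75)

    def test_center_roundtrip(self, small_grid):
        for row in range(3):
            for col in range(3):
                x, y = small_grid.cell_center(row, col)
                assert small_grid.cell_of(float(x), float(y)) == (row, col)

    def test_boundary_point_goes_south_east(self, small_grid):
        # point exactly on the boundary between columns 0/1 and rows 0/1
        x, y = 30.5, 30.5
        assert small_grid.cell_of(x, y) == (1, 1)
        eps = 1e-9
        assert small_grid.cell_of(x - eps, y + eps) == (0, 0)
        assert small_grid.cell_of(x + eps, y - eps) == (1, 1)

    def test_outside_extent_is_none(self, small_grid):
        assert small_grid.cell_of(29.9, 30.5) is None
        assert small_grid.cell_of(30.5, 29.4) is None


class TestAlignment:
    def test_alignment_is_equivalence(self, small_grid):
        twin = small_grid.like(small_grid.values * 2)
        other = RasterGrid(small_grid.values, small_grid.mask, 30.0, 31.0, 0.25)
        assert small_grid.aligned(small_grid)
        assert small_grid.aligned(twin) and twin.aligned(small_grid)
        assert not small_grid.aligned(other)

    def test_cross_layer_ops_fail_loudly(self, small_grid):
        other = RasterGrid(small_grid.values, small_grid.mask, 30.0, 31.0, 0.25)
        with pytest.raises(AlignmentError):
            small_grid.assert_aligned(other)


class TestOccurrences:
    def test_duplicates_collapse(self, small_grid):
        records = [(30.1, 30.9)] * 5
        assert len(occurrences_to_cells(records, small_grid)) == 1

    def test_distinct_cell_count_matches_brute_force(self, small_grid):
        rng = np.random.default_rng(42)
        records = [
            (30.0 + 1.5 * rng.random(), 29.5 + 1.5 * rng.random())
            for _ in range(14)
        ]
        expected = {small_grid.cell_of(x, y) for x, y in records}
        expected.discard(None)
        got = occurrences_to_cells(records, small_grid)
        assert got == expected

    def test_masked_and_outside_records_dropped(self, small_grid):
        small_grid.mask[0, 0] = True
        records = [(30.1, 30.9), (99.0, 99.0), (30.6, 30.9)]
        cells = occurrences_to_cells(records, small_grid)
        assert cells == {(0, 1)}

    def test_idempotent_under_center_remapping(self, small_grid):
        rng = np.random.default_rng(3)
        records = [(30.0 + 1.5 * rng.random(), 29.5 + 1.5 * rng.random())
                   for _ in range(30)]
        cells = occurrences_to_cells(records, small_grid)
        centers = [tuple(map(float, small_grid.cell_center(r, c))) for r, c in cells]
        assert occurrences_to_cells(centers, small_grid) == cells


class TestPointInPolygon:
    unit_square = [(0, 0), (1, 0), (1, 1), (0, 1)]

    @pytest.mark.parametrize(
        "pt,expected",
        [((0.5, 0.5), True), ((1.5, 0.5), False), ((1.0, 0.5), True),
         ((0.0, 0.0), True)],
    )
    def test_unit_square(self, pt, expected):
        assert point_in_polygon(*pt, self.unit_square) is expected

    def test_concave_notch_is_outside(self):
        # L-shape: notch at the top-right quadrant
        lshape = [(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)]
        assert point_in_polygon(1.5, 1.5, lshape) is False
        assert point_in_polygon(0.5, 1.5, lshape) is True
        assert _winding_inside(1.5, 1.5, lshape) is False
        assert _winding_inside(0.5, 1.5, lshape) is True

    def test_matches_winding_oracle_on_random_polygons(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            angles = np.sort(rng.uniform(0, 2 * math.pi, 7))
            radii = rng.uniform(0.5, 1.5, 7)
            poly = [(r * math.cos(a), r * math.sin(a)) for r, a in zip(radii, angles)]
            for _ in range(25):
                x, y = rng.uniform(-2, 2, 2)
                assert point_in_polygon(x, y, poly) == _winding_inside(x, y, poly)

    def test_degenerate_polygon_raises(self):
        with pytest.raises(GeometryError):
            point_in_polygon(0.0, 0.0, [(0, 0), (1, 1)])


class TestDistances:
    def test_haversine_one_degree_latitude(self):
        d = haversine_km(31.0, 28.0, 31.0, 29.0)
        assert d == pytest.approx(KM_PER_DEG, rel=1e-9)

    def test_distance_to_polygon_along_meridian(self):
        # square reserve; points due north of the top edge at known distances
        square = [(30.0, 28.0), (30.5, 28.0), (30.5, 28.5), (30.0, 28.5)]
        y49 = 28.5 + 49.0 / KM_PER_DEG
        y51 = 28.5 + 51.0 / KM_PER_DEG
        d49 = distance_to_polygon_km(30.25, y49, square)
        d51 = distance_to_polygon_km(30.25, y51, square)
        assert d49 == pytest.approx(49.0, rel=1e-6)
        assert d51 == pytest.approx(51.0, rel=1e-6)
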