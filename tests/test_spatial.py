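"""Distance transform, zone binning, area tabulation, ASCII grid I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swrisk.spatial import (
    AsciiGrid,
    GeometryError,
    WatershedGrid,
    Zone,
    ZoneExposure,
    assemble_grid,
    distance_to_stream,
    read_ascii_grid,
    read_zone_areas_csv,
    tabulate_zone_areas,
    write_ascii_grid,
    write_zone_areas_csv,
    zone_of,
)


def _grid(stream_mask, landuse=None, sub=None, cell_size=10.0):
    stream_mask = np.asarray(stream_mask, dtype=bool)
    if landuse is None:
        landuse = np.ones_like(stream_mask, dtype=int)
    if sub is None:
        sub = np.ones_like(stream_mask, dtype=int)
    return WatershedGrid(
        landuse=landuse, stream_mask=stream_mask,
        subwatershed_id=sub, cell_size=cell_size,
    )


def brute_force_distance(stream_mask: np.ndarray, cell_size: float) -> np.ndarray:
    """O(cells x stream cells) nearest-stream-cell distance oracle."""
    rows, cols = np.nonzero(stream_mask)
    stream_pts = np.stack([rows, cols], axis=1).astype(float)
    out = np.empty(stream_mask.shape)
    for i in range(stream_mask.shape[0]):
        for j in range(stream_mask.shape[1]):
            d2 = (stream_pts[:, 0] - i) ** 2 + (stream_pts[:, 1] - j) ** 2
            out[i, j] = np.sqrt(d2.min()) * cell_size
    return out


class TestDistanceToStream:
    def test_four_neighbour_distance_is_one_cell(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        d = distance_to_stream(_grid(mask, cell_size=10.0))
        assert d[1, 1] == 0.0
        assert d[0, 1] == pytest.approx(10.0)
        assert d[1, 0] == pytest.approx(10.0)

    def test_diagonal_neighbour_distance(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        d = distance_to_stream(_grid(mask, cell_size=10.0))
        assert d[0, 0] == pytest.approx(np.sqrt(2) * 10.0)

    def test_matches_brute_force_on_random_grid(self):
        rng = np.random.default_rng(7)
        mask = np.zeros((40, 40), dtype=bool)
        idx = rng.choice(1600, size=25, replace=False)
        mask.flat[idx] = True
        d = distance_to_stream(_grid(mask, cell_size=7.5))
        np.testing.assert_allclose(d, brute_force_distance(mask, 7.5), atol=1e-9)

    def test_adding_stream_cells_never_increases_distance(self):
        rng = np.random.default_rng(11)
        mask = np.zeros((30, 30), dtype=bool)
        mask.flat[rng.choice(900, size=10, replace=False)] = True
        d_before = distance_to_stream(_grid(mask))
        more = mask.copy()
        more.flat[rng.choice(900, size=20, replace=False)] = True
        d_after = distance_to_stream(_grid(more))
        assert (d_after <= d_before + 1e-9).all()

    def test_no_stream_cells_is_an_error(self):
        with pytest.raises(ValueError, match="no stream"):
            distance_to_stream(_grid(np.zeros((4, 4), dtype=bool)))


class TestZoneOf:
    @pytest.mark.parametrize(
        "distance,zone",
        [
            (0.0, Zone.ZONE_0_50),
            (50.0, Zone.ZONE_0_50),        # upper edge inclusive
            (50.001, Zone.ZONE_50_250),
            (250.0, Zone.ZONE_50_250),
            (250.001, Zone.ZONE_250_1000),
            (1000.0, Zone.ZONE_250_1000),
            (1000.001, Zone.ZONE_BEYOND_1000),
            (1200.0, Zone.ZONE_BEYOND_1000),
        ],
    )
    def test_bin_edges(self, distance, zone):
        assert zone_of(distance) is zone

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            zone_of(-1.0)

    @given(st.floats(0.0, 5000.0))
    @settings(deadline=None, max_examples=200)
    def test_bins_partition_nonnegative_reals(self, d):
        zones = [z for z in Zone if z.inner_m <= d <= z.outer_m or
                 (z.inner_m < d <= z.outer_m)]
        assert zone_of(d) in zones


class TestTabulateZoneAreas:
    def test_rectangle_against_analytic_band_overlap(self):
        """Straight vertical stream; a 300 m x 100 m tea rectangle starting
        20 m from it, on 10 m cells. Expected per-zone areas follow from
        counting which column centers fall in each distance band."""
        n = 100
        mask = np.zeros((n, n), dtype=bool)
        mask[:, 0] = True  # stream along the left edge
        landuse = np.ones((n, n), dtype=int)
        # columns 2..31: centers 20..310 m from the stream column; 10 rows
        landuse[10:20, 2:32] = 9
        grid = _grid(mask, landuse=landuse)
        exposures = {
            e.zone: e.activity_area_m2
            for e in tabulate_zone_areas(grid, activity_class=9)
        }
        # closed-form column counts: distance of column j is j*10 m
        # [0,50] -> j in {2..5}; (50,250] -> {6..25}; (250,1000] -> {26..31}
        assert exposures[Zone.ZONE_0_50] == 4 * 10 * 100.0
        assert exposures[Zone.ZONE_50_250] == 20 * 10 * 100.0
        assert exposures[Zone.ZONE_250_1000] == 6 * 10 * 100.0
        assert exposures[Zone.ZONE_BEYOND_1000] == 0.0
        assert sum(exposures.values()) == 300.0 * 100.0

    def test_absent_class_yields_four_zero_rows(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0] = True
        exposures = tabulate_zone_areas(_grid(mask), activity_class=42)
        assert len(exposures) == 4
        assert all(e.activity_area_m2 == 0.0 for e in exposures)

    def test_full_coverage_conserves_subwatershed_area(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 3] = True
        grid = _grid(mask)  # background class 1 everywhere
        exposures = tabulate_zone_areas(grid, activity_class=1)
        total = sum(e.activity_area_m2 for e in exposures)
        assert total == exposures[0].subwatershed_area_m2 == 64 * 100.0

    def test_conservation_across_random_subwatersheds(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((30, 30), dtype=bool)
        mask.flat[rng.choice(900, 12, replace=False)] = True
        landuse = rng.integers(1, 4, size=(30, 30))
        sub = rng.integers(1, 4, size=(30, 30))
        grid = _grid(mask, landuse=landuse, sub=sub)
        for cls in (1, 2, 3):
            exposures = tabulate_zone_areas(grid, activity_class=cls)
            for sid in ("1", "2", "3"):
                zone_sum = sum(
                    e.activity_area_m2 for e in exposures if e.subwatershed == sid
                )
                expected = ((landuse == cls) & (sub == int(sid))).sum() * 100.0
                assert zone_sum == expected


class TestZoneExposureInvariants:
    def test_activity_cannot_exceed_subwatershed(self):
        with pytest.raises(ValueError):
            ZoneExposure("A", 1, Zone.ZONE_0_50, 200.0, 100.0)

    def test_percent(self):
        e = ZoneExposure("A", 1, Zone.ZONE_0_50, 25.0, 100.0)
        assert e.percent == 25.0


class TestAsciiGridIO:
    def test_integer_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 9, size=(20, 20))
        layer = AsciiGrid(data=data, cell_size=10.0, xllcorner=100.0, yllcorner=-50.0)
        path = tmp_path / "layer.asc"
        write_ascii_grid(layer, path)
        back = read_ascii_grid(path)
        np.testing.assert_array_equal(back.data, data)
        assert back.cell_size == 10.0
        assert (back.xllcorner, back.yllcorner) == (100.0, -50.0)

    def test_nodata_cells_excluded_from_tabulation(self, tmp_path):
        landuse = np.ones((4, 4), dtype=int)
        landuse[0, :] = -9999  # NODATA strip
        stream = np.zeros((4, 4), dtype=int)
        stream[2, 2] = 1
        grid = assemble_grid(
            AsciiGrid(landuse, cell_size=10.0),
            AsciiGrid(stream, cell_size=10.0),
        )
        exposures = tabulate_zone_areas(grid, activity_class=1)
        assert exposures[0].subwatershed_area_m2 == 12 * 100.0
        assert sum(e.activity_area_m2 for e in exposures) == 12 * 100.0

    def test_mismatched_geometry_raises(self):
        a = AsciiGrid(np.ones((4, 4), dtype=int), cell_size=10.0)
        b = AsciiGrid(np.ones((4, 4), dtype=int), cell_size=20.0)
        with pytest.raises(GeometryError):
            assemble_grid(a, b)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 2\nnrows 2\n1 2\n3 4\n")
        with pytest.raises(GeometryError, match="missing"):
            read_ascii_grid(path)


def test_zone_area_csv_round_trip(tmp_path, tswa_zone_areas):
    path = tmp_path / "zones.csv"
    write_zone_areas_csv(tswa_zone_areas, path)
    back = read_zone_areas_csv(path)
    assert back == tswa_zone_areas
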