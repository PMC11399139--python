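"""Raster and metadata I/O: MTL parsing, GeoTIFF round-trips, summaries."""

import numpy as np
import pytest

from mptet.errors import EmptySummaryError, GridError, MetadataError
from mptet.scene_io import (
    GridSpec,
    SummaryRecord,
    parse_mtl,
    read_landsat_scene,
    read_raster,
    scene_summary,
    write_raster,
)


def _write_mtl(path, **overrides):
    keys = {
        "SUN_ELEVATION": "45.0",
        "DATE_ACQUIRED": "2022-12-17",
        "SCENE_CENTER_TIME": '"10:30:00.000000Z"',
    }
    keys.update(overrides)
    lines = ["GROUP = LANDSAT_METADATA_FILE"]
    lines += [f"  {k} = {v}" for k, v in keys.items() if v is not None]
    lines += ["END_GROUP = LANDSAT_METADATA_FILE", "END"]
    path.write_text("\n".join(lines))
    return path


def _write_bands(tmp_path, grid, value=0.2, shift_band=None):
    paths = {}
    for b in range(2, 8):
        g = grid
        if b == shift_band:
            gt = list(grid.geotransform)
            gt[0] += 15.0  # shifted origin
            g = GridSpec(
                width=grid.width, height=grid.height,
                geotransform=tuple(gt),
            )
        p = tmp_path / f"b{b}.tif"
        write_raster(np.full(grid.shape, value), g, p, units="reflectance")
        paths[b] = p
    return paths


class TestMtlAndSceneReading:
    def test_scene_metadata_derived_from_mtl(self, tmp_path):
        grid = GridSpec(width=8, height=8)
        bands = _write_bands(tmp_path, grid)
        mtl = _write_mtl(tmp_path / "MTL.txt")
        lst = tmp_path / "lst.tif"
        write_raster(np.full(grid.shape, 300.0), grid, lst, units="K")

        scene = read_landsat_scene(bands, mtl, lst)
        assert scene.meta.sun_elevation_deg == 45.0
        assert scene.meta.doy == 351  # 17 December of a non-leap year
        assert scene.meta.overpass_time == pytest.approx(10.5)

    def test_reflectance_rescaled_when_mtl_declares_scale(self, tmp_path):
        grid = GridSpec(width=8, height=8)
        bands = _write_bands(tmp_path, grid, value=10000.0)
        extra = {}
        for b in range(2, 8):
            extra[f"REFLECTANCE_MULT_BAND_{b}"] = "2.75e-05"
            extra[f"REFLECTANCE_ADD_BAND_{b}"] = "-0.2"
        mtl = _write_mtl(tmp_path / "MTL.txt", **extra)
        lst = tmp_path / "lst.tif"
        write_raster(np.full(grid.shape, 300.0), grid, lst, units="K")

        scene = read_landsat_scene(bands, mtl, lst)
        assert scene.reflectance.rho2[0, 0] == pytest.approx(0.075)

    def test_missing_sun_elevation_raises_metadata_error(self, tmp_path):
        grid = GridSpec(width=4, height=4)
        bands = _write_bands(tmp_path, grid)
        mtl = _write_mtl(tmp_path / "MTL.txt", SUN_ELEVATION=None)
        lst = tmp_path / "lst.tif"
        write_raster(np.full(grid.shape, 300.0), grid, lst)
        with pytest.raises(MetadataError, match="SUN_ELEVATION"):
            read_landsat_scene(bands, mtl, lst)

    def test_shifted_band_raises_grid_error_naming_files(self, tmp_path):
        grid = GridSpec(width=4, height=4)
        bands = _write_bands(tmp_path, grid, shift_band=3)
        mtl = _write_mtl(tmp_path / "MTL.txt")
        lst = tmp_path / "lst.tif"
        write_raster(np.full(grid.shape, 300.0), grid, lst)
        with pytest.raises(GridError, match="b3.tif"):
            read_landsat_scene(bands, mtl, lst)

    def test_nodata_unioned_across_bands(self, tmp_path):
        grid = GridSpec(width=4, height=4)
        bands = {}
        for b in range(2, 8):
            arr = np.full(grid.shape, 0.2)
            if b == 5:
                arr[1, 1] = np.nan
            p = tmp_path / f"b{b}.tif"
            write_raster(arr, grid, p)
            bands[b] = p
        mtl = _write_mtl(tmp_path / "MTL.txt")
        lst = tmp_path / "lst.tif"
        ts = np.full(grid.shape, 300.0)
        ts[2, 2] = np.nan
        write_raster(ts, grid, lst)

        scene = read_landsat_scene(bands, mtl, lst)
        valid = scene.valid_mask()
        assert not valid[1, 1] and not valid[2, 2]
        assert valid.sum() == 14
        # union: the band-5 hole is also a hole in band 2 and in LST
        assert np.isnan(scene.reflectance.rho2[1, 1])
        assert np.isnan(scene.ts_K[1, 1])

    def test_identical_inputs_give_identical_scenes(self, tmp_path):
        grid = GridSpec(width=6, height=6)
        bands = _write_bands(tmp_path, grid, value=0.31)
        mtl = _write_mtl(tmp_path / "MTL.txt")
        lst = tmp_path / "lst.tif"
        write_raster(np.full(grid.shape, 301.5), grid, lst)
        s1 = read_landsat_scene(bands, mtl, lst)
        s2 = read_landsat_scene(bands, mtl, lst)
        assert np.array_equal(s1.ts_K, s2.ts_K)
        assert all(
            np.array_equal(a, b)
            for a, b in zip(s1.reflectance.bands(), s2.reflectance.bands())
        )
        assert s1.meta == s2.meta and s1.grid == s2.grid


class TestRasterRoundTrip:
    def test_values_mask_and_grid_survive_round_trip(self, tmp_path):
        grid = GridSpec(width=10, height=10, geotransform=(500.0, 30.0, 0.0, 7000.0, 0.0, -30.0))
        arr = np.arange(100, dtype=float).reshape(10, 10)
        arr[[0, 3, 7], [1, 4, 9]] = np.nan
        p = tmp_path / "field.tif"
        write_raster(arr, grid, p, units="mm/day")
        back, grid2, units = read_raster(p)
        assert units == "mm/day"
        assert np.isnan(back).sum() == 3
        valid = np.isfinite(arr)
        np.testing.assert_array_equal(back[valid], arr[valid].astype(np.float32))
        assert grid2.shape == grid.shape
        assert grid2.geotransform == grid.geotransform

    def test_constant_raster_round_trips_exactly(self, tmp_path):
        grid = GridSpec(width=10, height=10)
        arr = np.full((10, 10), 2.5)
        p = tmp_path / "c.tif"
        write_raster(arr, grid, p)
        back, _, _ = read_raster(p)
        np.testing.assert_array_equal(back, arr)

    def test_nonconforming_field_rejected(self, tmp_path):
        grid = GridSpec(width=5, height=5)
        with pytest.raises(GridError):
            write_raster(np.zeros((4, 5)), grid, tmp_path / "bad.tif")


class TestSceneSummary:
    @pytest.mark.parametrize(
        "values, mask, expected",
        [
            (np.full((2, 2), 2.0), None, SummaryRecord(2.0, 2.0, 0.0, 4)),
            (
                np.array([[1.0, 2.0, 3.0]]),
                None,
                SummaryRecord(2.0, 3.0, 1.0, 3),
            ),
            (
                np.array([[1.0, 2.0], [3.0, 4.0]]),
                np.array([[True, True], [True, False]]),
                SummaryRecord(2.0, 3.0, 1.0, 3),
            ),
        ],
    )
    def test_statistics_over_masked_valid_pixels(self, values, mask, expected):
        rec = scene_summary(values, mask)
        assert rec.mean == pytest.approx(expected.mean)
        assert rec.max == pytest.approx(expected.max)
        assert rec.sd == pytest.approx(expected.sd)
        assert rec.n_valid == expected.n_valid

    def test_empty_region_raises(self):
        with pytest.raises(EmptySummaryError):
            scene_summary(np.full((3, 3), np.nan))

    def test_mean_bounded_by_extremes(self, rng):
        arr = rng.normal(size=(40, 40))
        arr[rng.random((40, 40)) < 0.1] = np.nan
        rec = scene_summary(arr)
        assert np.nanmin(arr) <= rec.mean <= np.nanmax(arr)
        assert rec.max == pytest.approx(np.nanmax(arr))

    def test_mtl_parser_strips_quotes_and_groups(self, tmp_path):
        p = _write_mtl(tmp_path / "MTL.txt")
        mtl = parse_mtl(p)
        assert mtl["SCENE_CENTER_TIME"] == "10:30:00.000000Z"
        assert "GROUP" not in mtl
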