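"""Scene input/output: Landsat-style band rasters, MTL metadata, masks.

Rasters are held in memory as float64 arrays with NaN marking invalid
pixels; the nodata sentinel exists only at the file boundary.  All rasters
attached to one :class:`Scene` share a single :class:`GridSpec` —
bit-identical geotransform and CRS — because the pipeline does no
reprojection or resampling.

GeoTIFF files are read and written through :mod:`tifffile` with the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA)
plus a small JSON payload in the image description carrying the CRS
identifier and the physical units of the field.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import EmptySummaryError, GridError, MetadataError

__all__ = [
    "GridSpec",
    "SceneMeta",
    "ReflectanceStack",
    "Scene",
    "parse_mtl",
    "read_landsat_scene",
    "read_raster",
    "write_raster",
    "scene_summary",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Shared raster grid contract.

    ``geotransform`` follows the GDAL convention
    ``(x0, dx, 0, y0, 0, -dy)`` with pixel-center registration, row-major
    storage and a top-left origin.
    """

    width: int
    height: int
    pixel_size: float = 30.0
    crs_id: str = "EPSG:32644"
    geotransform: tuple[float, float, float, float, float, float] = (
        0.0, 30.0, 0.0, 0.0, 0.0, -30.0,
    )
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise GridError(
                f"grid dimensions must be positive, got {self.width}x{self.height}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def conforms(self, arr: np.ndarray) -> bool:
        return arr.shape == self.shape

    def require(self, arr: np.ndarray, name: str = "raster") -> None:
        if not self.conforms(arr):
            raise GridError(
                f"{name} shape {arr.shape} does not conform to grid {self.shape}"
            )


@dataclass(frozen=True)
class SceneMeta:
    """Per-scene acquisition metadata from the MTL file."""

    acquisition_date: _dt.date
    doy: int
    overpass_time: float  # local solar time, hours
    sun_elevation_deg: float
    sensor_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.doy <= 366:
            raise MetadataError(f"day of year {self.doy} outside 1..366")
        if not 0.0 < self.sun_elevation_deg <= 90.0:
            raise MetadataError(
                f"sun elevation {self.sun_elevation_deg} deg outside (0, 90]"
            )
        if not 0.0 <= self.overpass_time < 24.0:
            raise MetadataError(
                f"overpass time {self.overpass_time} h outside [0, 24)"
            )


@dataclass
class ReflectanceStack:
    """Surface reflectance for Landsat optical bands 2-7, unitless [0, 1].

    Invalid pixels are NaN in every band (nodata is unioned across bands
    at read time so no derived field ever mixes valid and invalid inputs).
    """

    rho2: np.ndarray
    rho3: np.ndarray
    rho4: np.ndarray
    rho5: np.ndarray
    rho6: np.ndarray
    rho7: np.ndarray

    def bands(self) -> tuple[np.ndarray, ...]:
        return (self.rho2, self.rho3, self.rho4, self.rho5, self.rho6, self.rho7)

    def valid_mask(self) -> np.ndarray:
        m = np.isfinite(self.bands()[0])
        for b in self.bands()[1:]:
            m &= np.isfinite(b)
        return m


@dataclass
class Scene:
    """The raster input bundle: reflectance + LST on one grid."""

    grid: GridSpec
    meta: SceneMeta
    reflectance: ReflectanceStack
    ts_K: np.ndarray
    aoi_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for i, b in enumerate(self.reflectance.bands(), start=2):
            self.grid.require(b, f"band {i}")
        self.grid.require(self.ts_K, "ts_K")
        if self.aoi_mask is not None:
            self.grid.require(self.aoi_mask, "aoi_mask")

    def valid_mask(self) -> np.ndarray:
        """True where every input (all bands + LST + AOI) is valid."""
        m = self.reflectance.valid_mask() & np.isfinite(self.ts_K)
        if self.aoi_mask is not None:
            m &= self.aoi_mask.astype(bool)
        return m


# ---------------------------------------------------------------------------
# MTL metadata

_MTL_LINE = re.compile(r"^\s*([A-Z0-9_]+)\s*=\s*(.+?)\s*$")

REQUIRED_MTL_KEYS = ("SUN_ELEVATION", "DATE_ACQUIRED", "SCENE_CENTER_TIME")


def parse_mtl(mtl_path: str | Path) -> dict[str, str]:
    """Parse a Collection-2 style ``KEY = value`` MTL text file.

    GROUP/END_GROUP structure is flattened; values keep their text form
    with surrounding quotes stripped.
    """
    out: dict[str, str] = {}
    for line in Path(mtl_path).read_text().splitlines():
        m = _MTL_LINE.match(line)
        if not m:
            continue
        key, value = m.group(1), m.group(2).strip().strip('"')
        if key in ("GROUP", "END_GROUP") or key == "END":
            continue
        out[key] = value
    return out


def _parse_center_time(text: str) -> float:
    """``HH:MM:SS[.ffff][Z]`` -> decimal hours."""
    text = text.strip().rstrip("Zz")
    parts = text.split(":")
    if len(parts) != 3:
        raise MetadataError(f"cannot parse SCENE_CENTER_TIME {text!r}")
    h, m, s = int(parts[0]), int(parts[1]), float(parts[2])
    return h + m / 60.0 + s / 3600.0


def scene_meta_from_mtl(mtl: Mapping[str, str]) -> SceneMeta:
    for key in REQUIRED_MTL_KEYS:
        if key not in mtl:
            raise MetadataError(f"MTL file is missing required key {key}")
    date = _dt.date.fromisoformat(mtl["DATE_ACQUIRED"])
    return SceneMeta(
        acquisition_date=date,
        doy=date.timetuple().tm_yday,
        overpass_time=_parse_center_time(mtl["SCENE_CENTER_TIME"]),
        sun_elevation_deg=float(mtl["SUN_ELEVATION"]),
        sensor_id=mtl.get("SPACECRAFT_ID", ""),
    )


# ---------------------------------------------------------------------------
# Raster I/O

def write_raster(
    field_arr: np.ndarray,
    grid: GridSpec,
    path: str | Path,
    units: str = "",
) -> None:
    """Write a single-band float32 GeoTIFF with nodata and a units tag.

    NaN pixels are replaced with ``grid.nodata_value`` on disk.
    """
    grid.require(field_arr, "field")
    data = np.asarray(field_arr, dtype=np.float32).copy()
    data[~np.isfinite(data)] = np.float32(grid.nodata_value)
    gt = grid.geotransform
    desc = json.dumps({"crs_id": grid.crs_id, "units": units})
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(gt[1]), abs(gt[5]), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, gt[0], gt[3], 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata_value)),
    ]
    tifffile.imwrite(
        str(path), data, description=desc, extratags=extratags, photometric="minisblack"
    )


def read_raster(path: str | Path) -> tuple[np.ndarray, GridSpec, str]:
    """Read a single-band GeoTIFF -> (float64 array with NaN nodata, grid, units)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise GridError(f"{path}: expected a single-band raster, got shape {data.shape}")
        tags = page.tags
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        px = py = 30.0
        if _TAG_PIXEL_SCALE in tags:
            scale = tags[_TAG_PIXEL_SCALE].value
            px, py = float(scale[0]), float(scale[1])
        x0 = y0 = 0.0
        if _TAG_TIEPOINT in tags:
            tp = tags[_TAG_TIEPOINT].value
            x0, y0 = float(tp[3]), float(tp[4])
        crs_id, units = "", ""
        if page.description:
            try:
                meta = json.loads(page.description)
                crs_id = meta.get("crs_id", "")
                units = meta.get("units", "")
            except (json.JSONDecodeError, AttributeError):
                pass
    arr = np.asarray(data, dtype=np.float64)
    arr[arr == nodata] = np.nan
    grid = GridSpec(
        width=arr.shape[1],
        height=arr.shape[0],
        pixel_size=px,
        crs_id=crs_id or "EPSG:32644",
        geotransform=(x0, px, 0.0, y0, 0.0, -py),
        nodata_value=nodata,
    )
    return arr, grid, units


def _grids_match(a: GridSpec, b: GridSpec) -> bool:
    return (
        a.shape == b.shape
        and a.geotransform == b.geotransform
        and a.crs_id == b.crs_id
    )


def read_landsat_scene(
    band_paths: Mapping[int, str | Path] | Sequence[str | Path],
    mtl_path: str | Path,
    lst_path: str | Path,
    aoi_path: str | Path | None = None,
) -> Scene:
    """Assemble a :class:`Scene` from per-band GeoTIFFs, an MTL file and an LST raster.

    ``band_paths`` maps Landsat band number (2-7) to file path, or is a
    sequence of six paths in band order.  Reflectance is rescaled to
    physical units when the MTL declares ``REFLECTANCE_MULT_BAND_n`` /
    ``REFLECTANCE_ADD_BAND_n``; otherwise inputs are taken as already
    being surface reflectance.  The nodata mask of the scene is the union
    of the per-band masks (a pixel invalid anywhere is invalid everywhere).
    """
    if not isinstance(band_paths, Mapping):
        band_paths = {i + 2: p for i, p in enumerate(band_paths)}
    missing = [b for b in range(2, 8) if b not in band_paths]
    if missing:
        raise MetadataError(f"band paths missing for bands {missing}")

    mtl = parse_mtl(mtl_path)
    meta = scene_meta_from_mtl(mtl)

    bands: dict[int, np.ndarray] = {}
    grid: GridSpec | None = None
    first_path: str | Path | None = None
    for b in range(2, 8):
        arr, g, _ = read_raster(band_paths[b])
        mult = float(mtl.get(f"REFLECTANCE_MULT_BAND_{b}", 1.0))
        add = float(mtl.get(f"REFLECTANCE_ADD_BAND_{b}", 0.0))
        if (mult, add) != (1.0, 0.0):
            arr = arr * mult + add
        if grid is None:
            grid, first_path = g, band_paths[b]
        elif not _grids_match(grid, g):
            raise GridError(
                f"grid mismatch between {first_path} and {band_paths[b]}"
            )
        bands[b] = arr

    ts_K, g_ts, _ = read_raster(lst_path)
    assert grid is not None
    if not _grids_match(grid, g_ts):
        raise GridError(f"grid mismatch between {first_path} and {lst_path}")

    aoi = None
    if aoi_path is not None:
        aoi_arr, g_aoi, _ = read_raster(aoi_path)
        if not _grids_match(grid, g_aoi):
            raise GridError(f"grid mismatch between {first_path} and {aoi_path}")
        aoi = np.nan_to_num(aoi_arr, nan=0.0) > 0

    # union of nodata across all inputs
    invalid = ~np.isfinite(ts_K)
    for arr in bands.values():
        invalid |= ~np.isfinite(arr)
    for arr in bands.values():
        arr[invalid] = np.nan
    ts_K = ts_K.copy()
    ts_K[invalid] = np.nan

    stack = ReflectanceStack(*(bands[b] for b in range(2, 8)))
    return Scene(grid=grid, meta=meta, reflectance=stack, ts_K=ts_K, aoi_mask=aoi)


# ---------------------------------------------------------------------------
# Summaries

@dataclass(frozen=True)
class SummaryRecord:
    mean: float
    max: float
    sd: float  # sample SD, n-1 denominator
    n_valid: int


def scene_summary(
    field_arr: np.ndarray, mask: np.ndarray | None = None
) -> SummaryRecord:
    """Mean/max/sample-SD over valid (finite, masked-in) pixels.

    Raises :class:`EmptySummaryError` when no valid pixel remains.
    """
    values = np.asarray(field_arr, dtype=float)
    valid = np.isfinite(values)
    if mask is not None:
        if mask.shape != values.shape:
            raise GridError(
                f"mask shape {mask.shape} does not match field {values.shape}"
            )
        valid &= mask.astype(bool)
    vals = values[valid]
    if vals.size == 0:
        raise EmptySummaryError("no valid pixels in summary region")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return SummaryRecord(
        mean=float(vals.mean()), max=float(vals.max()), sd=sd, n_valid=int(vals.size)
    )
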