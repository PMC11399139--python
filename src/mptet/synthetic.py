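"""Self-contained synthetic Landsat-like scenes with known ground truth.

The generator emulates the vegetation-gradient structure of an
agricultural district at overpass time: a populated Ts-Fr triangle whose
dry edge decreases with vegetation cover and whose wet edge is a
horizontal line, with surface temperature anti-correlated with
vegetation fraction.  Every pixel carries a known Priestley-Taylor
coefficient phi_true, placed by inverting the two-step interpolation, so
edge fitting and phi retrieval can be validated end to end.

Reflectance synthesis mixes fixed soil and full-canopy endmember spectra.
The red and NIR bands are constructed so that the pixel NDVI is *exactly*
linear in the mixing weight sqrt(Fr); with the generator's NDVI scaling
bounds (0.1 soil, 0.9 vegetation) the standard squared-rescaled-NDVI
vegetation fraction then recovers Fr_true exactly.  The remaining bands
are linear endmember mixtures chosen to keep broadband albedo in the
realistic 0.05-0.4 range.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import CONSTANTS
from .errors import GenerationError
from .evaluation import PairedSeries
from .scene_io import (
    GridSpec,
    ReflectanceStack,
    Scene,
    SceneMeta,
    write_raster,
)
from .triangle import EdgeModel

__all__ = [
    "TriangleParams",
    "SyntheticTruth",
    "SOIL_ENDMEMBER",
    "VEGETATION_ENDMEMBER",
    "generate_triangle_scene",
    "write_scene_to_dir",
    "generate_validation_pairs",
]

# Endmember surface-reflectance spectra for bands 2..7.
# Soil NDVI = (0.22-0.18)/(0.22+0.18) = 0.10; canopy NDVI = (0.57-0.03)/0.60 = 0.90.
SOIL_ENDMEMBER = (0.10, 0.14, 0.18, 0.22, 0.30, 0.25)
VEGETATION_ENDMEMBER = (0.04, 0.06, 0.03, 0.57, 0.20, 0.10)

NDVI_SOIL = 0.1
NDVI_VEG = 0.9


@dataclass(frozen=True)
class TriangleParams:
    """Parameters of the synthetic Ts-Fr triangle.

    Defaults describe a late-winter/early-spring cropland scene: dry edge
    320 K at bare soil falling 15 K per unit vegetation fraction, wet
    edge at 295 K, and 0.5 K of sensor/sub-pixel temperature noise.
    ``fr_distribution`` is "uniform" or a ``("beta", a, b)`` tuple.
    ``outside_fraction`` deliberately places that fraction of pixels
    outside the triangle (hotter than the dry edge or cooler than the wet
    edge) to exercise clipping.
    """

    n_rows: int = 200
    n_cols: int = 200
    dry_intercept_K: float = 320.0
    dry_slope_K: float = -15.0
    t_min_K: float = 295.0
    fr_distribution: tuple = ("uniform",)
    ts_noise_sd_K: float = 0.5
    seed: int = 0
    outside_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.dry_slope_K > 0:
            raise GenerationError("dry_slope_K must be <= 0")
        if self.dry_intercept_K + self.dry_slope_K <= self.t_min_K:
            raise GenerationError(
                "dry edge must stay above the wet edge over Fr in [0, 1]"
            )
        if self.ts_noise_sd_K < 0:
            raise GenerationError("ts_noise_sd_K must be >= 0")
        if not 0.0 <= self.outside_fraction < 1.0:
            raise GenerationError("outside_fraction must be in [0, 1)")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise GenerationError("grid dimensions must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated scene."""

    phi_true: np.ndarray
    fr_true: np.ndarray
    edges_true: EdgeModel
    ndvi_bounds: tuple[float, float] = (NDVI_SOIL, NDVI_VEG)


def _draw_fr(params: TriangleParams, rng: np.random.Generator) -> np.ndarray:
    shape = (params.n_rows, params.n_cols)
    dist = params.fr_distribution
    if dist[0] == "uniform":
        return rng.uniform(0.0, 1.0, size=shape)
    if dist[0] == "beta":
        return rng.beta(dist[1], dist[2], size=shape)
    if dist[0] == "constant":
        return np.full(shape, float(dist[1]))
    raise GenerationError(f"unknown fr_distribution {dist!r}")


def generate_triangle_scene(
    params: TriangleParams,
    meta: SceneMeta | None = None,
) -> tuple[Scene, SyntheticTruth]:
    """Generate one scene with known per-pixel phi.

    Per pixel: draw Fr from ``fr_distribution``; draw phi_true uniformly
    in [1.26 Fr, 1.26] (so the pixel lies inside the triangle); place the
    surface temperature by inverting the two-step interpolation

        Ts = Tmax(Fr) - (phi - phi_min)/(1.26 - phi_min) * (Tmax(Fr) - Tmin)

    with phi_min = 1.26 Fr; add Gaussian noise of SD ``ts_noise_sd_K``.
    A fixed seed makes the scene bit-reproducible.
    """
    rng = np.random.default_rng(params.seed)
    phi_max = CONSTANTS.phi_max

    fr = _draw_fr(params, rng)
    phi_min = phi_max * fr
    phi_true = rng.uniform(phi_min, phi_max)

    t_max = params.dry_intercept_K + params.dry_slope_K * fr
    gap = phi_max - phi_min
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(gap > 1e-12, (phi_true - phi_min) / gap, 1.0)
    ts = t_max - frac * (t_max - params.t_min_K)

    if params.outside_fraction > 0:
        n = ts.size
        k = int(round(params.outside_fraction * n))
        idx = rng.choice(n, size=k, replace=False)
        flat = ts.ravel()
        offsets = rng.uniform(1.0, 5.0, size=k) * np.where(
            rng.random(k) < 0.5, 1.0, -1.0
        )
        # push above the local dry edge or below the wet edge
        hot = offsets > 0
        flat[idx[hot]] = t_max.ravel()[idx[hot]] + offsets[hot]
        flat[idx[~hot]] = params.t_min_K + offsets[~hot]
        ts = flat.reshape(ts.shape)

    if params.ts_noise_sd_K > 0:
        ts = ts + rng.normal(0.0, params.ts_noise_sd_K, size=ts.shape)

    # --- reflectance synthesis: NDVI exactly linear in w = sqrt(Fr)
    w = np.sqrt(fr)
    ndvi_t = NDVI_SOIL + (NDVI_VEG - NDVI_SOIL) * w
    red_soil, nir_soil = SOIL_ENDMEMBER[2], SOIL_ENDMEMBER[3]
    red_veg, nir_veg = VEGETATION_ENDMEMBER[2], VEGETATION_ENDMEMBER[3]
    s = (red_soil + nir_soil) + ((red_veg + nir_veg) - (red_soil + nir_soil)) * w
    nir = s * (1.0 + ndvi_t) / 2.0
    red = s * (1.0 - ndvi_t) / 2.0
    other = {
        b: SOIL_ENDMEMBER[i] + (VEGETATION_ENDMEMBER[i] - SOIL_ENDMEMBER[i]) * w
        for i, b in ((0, 2), (1, 3), (4, 6), (5, 7))
    }
    stack = ReflectanceStack(
        rho2=other[2], rho3=other[3], rho4=red, rho5=nir, rho6=other[6], rho7=other[7]
    )

    if meta is None:
        date = _dt.date(2023, 3, 15)
        meta = SceneMeta(
            acquisition_date=date,
            doy=date.timetuple().tm_yday,
            overpass_time=10.5,
            sun_elevation_deg=50.0,
            sensor_id="SYNTHETIC",
        )
    grid = GridSpec(width=params.n_cols, height=params.n_rows)
    scene = Scene(grid=grid, meta=meta, reflectance=stack, ts_K=ts)
    truth = SyntheticTruth(
        phi_true=phi_true,
        fr_true=fr,
        edges_true=EdgeModel(
            dry_intercept=params.dry_intercept_K,
            dry_slope=params.dry_slope_K,
            t_min=params.t_min_K,
        ),
    )
    return scene, truth


def write_scene_to_dir(scene: Scene, out_dir: str | Path) -> dict[str, Path]:
    """Write a scene as six band GeoTIFFs, an LST GeoTIFF and a minimal MTL.

    Returns the paths so the full reader path can be exercised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for b, arr in zip(range(2, 8), scene.reflectance.bands()):
        p = out / f"band{b}.tif"
        write_raster(arr, scene.grid, p, units="reflectance")
        paths[f"band{b}"] = p
    lst = out / "lst.tif"
    write_raster(scene.ts_K, scene.grid, lst, units="K")
    paths["lst"] = lst

    m = scene.meta
    hh = int(m.overpass_time)
    mm = int(round((m.overpass_time - hh) * 60))
    mtl = out / "MTL.txt"
    mtl.write_text(
        "GROUP = LANDSAT_METADATA_FILE\n"
        "  GROUP = IMAGE_ATTRIBUTES\n"
        f"    SPACECRAFT_ID = \"{m.sensor_id or 'SYNTHETIC'}\"\n"
        f"    DATE_ACQUIRED = {m.acquisition_date.isoformat()}\n"
        f"    SCENE_CENTER_TIME = \"{hh:02d}:{mm:02d}:00.000000Z\"\n"
        f"    SUN_ELEVATION = {m.sun_elevation_deg}\n"
        "  END_GROUP = IMAGE_ATTRIBUTES\n"
        "END_GROUP = LANDSAT_METADATA_FILE\n"
        "END\n"
    )
    paths["mtl"] = mtl
    return paths


def generate_validation_pairs(
    n: int,
    bias: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PairedSeries:
    """Paired observed/predicted daily ET series with injected error.

    Observed values follow a seasonal ramp from 1.3 to 3.7 mm day^-1 (the
    winter-to-spring range of daily mean ET over an irrigated cropland
    district); predicted = observed + bias + N(0, noise_sd).  With the
    MBE convention mean(observed - predicted), an injected bias of +b
    yields MBE = -b.
    """
    if n < 2:
        raise GenerationError("need at least 2 pairs")
    rng = np.random.default_rng(seed)
    observed = np.linspace(1.3, 3.7, n)
    predicted = observed + bias + rng.normal(0.0, noise_sd, size=n)
    start = _dt.date(2022, 12, 15)
    labels = [(start + _dt.timedelta(days=16 * i)).isoformat() for i in range(n)]
    return PairedSeries(observed=observed, predicted=predicted, labels=labels)
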