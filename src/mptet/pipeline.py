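"""Scene-to-ET orchestration: read -> atmosphere -> radiation -> triangle -> fluxes.

`run_scene` executes the full workflow for one scene and writes every
intermediate raster, the fitted edge model, a district-style summary row,
and a manifest with input paths, the parameters actually used, and
checksums of all outputs.  Everything it computes is reproducible by
direct library calls; the CLI is a thin wrapper over this module.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import CONSTANTS
from .errors import ConfigError, MptetError
from .evaluation import EvalReport, evaluate, read_pairs_csv
from .fluxes import (
    UpscalingConfig,
    daily_available_energy,
    daily_et,
    evaporative_fraction,
    instantaneous_et,
    latent_heat_flux,
    soil_heat_flux,
)
from .radiation import (
    broadband_albedo,
    longwave_down,
    longwave_up,
    net_radiation,
    shortwave_down,
    surface_emissivity,
)
from .scene_io import Scene, read_landsat_scene, scene_summary, write_raster
from .solar import MeteoSnapshot, atmosphere_at_overpass
from .triangle import (
    EdgeFitConfig,
    EdgeModel,
    fit_edges,
    ndvi,
    ndvi_bounds,
    phi_map,
    vegetation_fraction,
)

__all__ = ["RunConfig", "run_scene", "run_validate", "compute_scene_fluxes"]


@dataclass
class RunConfig:
    """Validated configuration for a single-scene run."""

    # inputs
    band_paths: dict[int, str] = field(default_factory=dict)
    mtl_path: str = ""
    lst_path: str = ""
    aoi_path: str | None = None
    # meteorology at overpass
    ta_K: float = 300.0
    pair_kPa: float = 100.0
    ea_kPa: float | None = None
    tdew_K: float | None = None
    kt: float = 1.0
    # geometry / upscaling
    latitude_deg: float = 29.0
    overpass_time_local: float | None = None  # overrides the MTL scene time
    alpha_upscale: float = CONSTANTS.alpha_upscale
    # triangle options
    ndvi_min: float | None = None  # fixed scaling bounds; None -> percentiles
    ndvi_max: float | None = None
    ndvi_lo_pct: float = 2.0
    ndvi_hi_pct: float = 98.0
    edge_fit: EdgeFitConfig = field(default_factory=EdgeFitConfig)
    # output
    outdir: str = "mptet_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        elif path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "band_paths" in raw:
            raw["band_paths"] = {int(k): str(v) for k, v in raw["band_paths"].items()}
        if "edge_fit" in raw and isinstance(raw["edge_fit"], dict):
            raw["edge_fit"] = EdgeFitConfig(**raw["edge_fit"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def validate_inputs(self) -> None:
        missing = [b for b in range(2, 8) if b not in self.band_paths]
        if missing:
            raise ConfigError(f"band_paths missing bands {missing}")
        for b, p in self.band_paths.items():
            if not Path(p).exists():
                raise ConfigError(f"band_paths[{b}]: file not found: {p}")
        if not self.mtl_path or not Path(self.mtl_path).exists():
            raise ConfigError(f"mtl_path: file not found: {self.mtl_path!r}")
        if not self.lst_path or not Path(self.lst_path).exists():
            raise ConfigError(f"lst_path: file not found: {self.lst_path!r}")
        if self.aoi_path is not None and not Path(self.aoi_path).exists():
            raise ConfigError(f"aoi_path: file not found: {self.aoi_path}")

    def meteo(self) -> MeteoSnapshot:
        return MeteoSnapshot(
            ta_K=self.ta_K,
            pair_kPa=self.pair_kPa,
            ea_kPa=self.ea_kPa,
            tdew_K=self.tdew_K,
            kt=self.kt,
        )


def compute_scene_fluxes(
    scene: Scene, config: RunConfig
) -> tuple[dict[str, np.ndarray], EdgeModel, dict]:
    """Run the flux chain on an in-memory scene.

    Returns (named rasters, fitted edge model, scalar diagnostics).
    """
    meteo = config.meteo()
    meta = scene.meta
    if config.overpass_time_local is not None:
        meta = dataclasses.replace(meta, overpass_time=config.overpass_time_local)

    atm = atmosphere_at_overpass(meteo, meta.doy, meta.sun_elevation_deg)

    alb = broadband_albedo(scene.reflectance)
    nd = ndvi(scene.reflectance.rho4, scene.reflectance.rho5)
    eps0 = surface_emissivity(nd)
    rs = shortwave_down(atm)
    rld = longwave_down(atm.eps_a, meteo.ta_K)
    rlu = longwave_up(eps0, scene.ts_K)
    rn = net_radiation(alb, rs, rld, rlu, eps0)

    if config.ndvi_min is not None and config.ndvi_max is not None:
        nd_min, nd_max = config.ndvi_min, config.ndvi_max
    else:
        nd_min, nd_max = ndvi_bounds(nd, config.ndvi_lo_pct, config.ndvi_hi_pct)
    fr = vegetation_fraction(nd, nd_min, nd_max)

    fit_mask = scene.valid_mask() & (nd > 0)  # water excluded from edge fit
    edges = fit_edges(
        np.where(fit_mask, scene.ts_K, np.nan),
        np.where(fit_mask, fr, np.nan),
        config.edge_fit,
    )
    phi_field = phi_map(scene.ts_K, fr, edges)

    g = soil_heat_flux(rn, scene.ts_K, alb, nd)
    le = latent_heat_flux(
        phi_field.phi, rn, g, atm.delta_kPa_per_C, atm.gamma_kPa_per_C
    )
    ef = evaporative_fraction(le, rn, g)
    et_i = instantaneous_et(le)
    upscale = UpscalingConfig(
        alpha_upscale=config.alpha_upscale, latitude_deg=config.latitude_deg
    )
    energy_d = daily_available_energy(rn, g, meta, upscale)
    et_d = daily_et(ef, energy_d, upscale)

    invalid = ~scene.valid_mask()
    rasters = {
        "albedo": alb,
        "ndvi": nd,
        "rn": rn,
        "g": g,
        "phi": phi_field.phi,
        "le": le,
        "ef": ef,
        "et_i": et_i,
        "et_d": et_d,
    }
    for arr in rasters.values():
        arr[invalid] = np.nan

    diagnostics = {
        "atmosphere": dataclasses.asdict(atm),
        "rs_down_W_m2": rs,
        "rl_down_W_m2": rld,
        "ndvi_bounds": [nd_min, nd_max],
        "negative_available_energy_pixels": int(
            np.nansum((rn - g) <= 0)
        ),
    }
    return rasters, edges, diagnostics


RASTER_UNITS = {
    "albedo": "unitless",
    "ndvi": "unitless",
    "rn": "W/m^2",
    "g": "W/m^2",
    "phi": "unitless",
    "le": "W/m^2",
    "ef": "unitless",
    "et_i": "mm/hour",
    "et_d": "mm/day",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_scene(config: RunConfig, scene: Scene | None = None) -> dict:
    """Execute the full workflow and write all outputs.

    ``scene`` may be supplied directly (synthetic mode); otherwise the
    configured files are read.  Returns the manifest dict.  On any stage
    failure, partially written outputs are removed before re-raising.
    """
    if scene is None:
        config.validate_inputs()
        scene = read_landsat_scene(
            config.band_paths, config.mtl_path, config.lst_path, config.aoi_path
        )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        rasters, edges, diagnostics = compute_scene_fluxes(scene, config)

        raster_paths: dict[str, str] = {}
        for name, arr in rasters.items():
            p = outdir / f"{name}.tif"
            write_raster(arr, scene.grid, p, units=RASTER_UNITS[name])
            written.append(p)
            raster_paths[name] = str(p)

        edges_path = outdir / "edges.json"
        edges.to_json(edges_path)
        written.append(edges_path)

        # Table-style summary row: daily ET statistics over the valid AOI
        summary = scene_summary(rasters["et_d"])
        summary_path = outdir / "summary.csv"
        pd.DataFrame(
            [
                {
                    "date": scene.meta.acquisition_date.isoformat(),
                    "field": "et_d",
                    "mean": summary.mean,
                    "max": summary.max,
                    "sd": summary.sd,
                    "n_valid": summary.n_valid,
                }
            ]
        ).to_csv(summary_path, index=False)
        written.append(summary_path)

        manifest = {
            "software": {"name": "mptet", "version": __version__},
            "inputs": {
                "band_paths": {str(k): str(v) for k, v in config.band_paths.items()},
                "mtl_path": config.mtl_path,
                "lst_path": config.lst_path,
                "aoi_path": config.aoi_path,
            },
            "parameters": {
                "ta_K": config.ta_K,
                "pair_kPa": config.pair_kPa,
                "ea_kPa": config.ea_kPa,
                "tdew_K": config.tdew_K,
                "kt": config.kt,
                "latitude_deg": config.latitude_deg,
                "alpha_upscale": config.alpha_upscale,
                "lambda_MJ_per_kg": CONSTANTS.lambda_MJ_per_kg,
                "phi_max": CONSTANTS.phi_max,
                "edge_fit": dataclasses.asdict(config.edge_fit),
                "ndvi_bounds": diagnostics["ndvi_bounds"],
            },
            "diagnostics": {
                k: v for k, v in diagnostics.items() if k != "atmosphere"
            },
            "atmosphere": diagnostics["atmosphere"],
            "edges": {
                "dry_intercept": edges.dry_intercept,
                "dry_slope": edges.dry_slope,
                "t_min": edges.t_min,
            },
            "rasters": raster_paths,
            "summary_csv": str(summary_path),
            "checksums": {str(p): _sha256(p) for p in written},
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        return manifest
    except MptetError:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def run_validate(pairs_path: str | Path, report_path: str | Path | None = None) -> EvalReport:
    """Evaluate a paired observed/predicted CSV and optionally write the report."""
    pairs = read_pairs_csv(pairs_path)
    report = evaluate(pairs)
    if report_path is not None:
        report.to_json(report_path)
    return report
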