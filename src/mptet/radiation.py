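"""Per-pixel radiation balance: shortwave, longwave, and net radiation.

Incoming shortwave and longwave are scene scalars (single overpass
meteorology and sun geometry); outgoing longwave and net radiation are
per-pixel rasters.  NaN marks invalid pixels and propagates through all
arithmetic.
"""

from __future__ import annotations

import numpy as np

from .constants import CONSTANTS, PhysicalConstants
from .scene_io import ReflectanceStack
from .solar import AtmosphereState

__all__ = [
    "broadband_albedo",
    "shortwave_down",
    "longwave_down",
    "surface_emissivity",
    "longwave_up",
    "net_radiation",
]

# Broadband albedo weights for Landsat 8/9 OLI bands 2-7 (Tasumi-style
# at-surface weighting; the six weights sum to 1.000).
ALBEDO_WEIGHTS = (0.254, 0.149, 0.147, 0.311, 0.103, 0.036)

#: Broadband emissivity assigned to water-class pixels (NDVI <= 0).
WATER_EMISSIVITY = 0.985
#: Lower clip on the log-law emissivity as NDVI -> 0+.
EMISSIVITY_FLOOR = 0.9


def broadband_albedo(reflectance: ReflectanceStack) -> np.ndarray:
    """Broadband surface albedo as a weighted sum of bands 2-7.

    alpha = 0.254 rho2 + 0.149 rho3 + 0.147 rho4 + 0.311 rho5
          + 0.103 rho6 + 0.036 rho7
    """
    bands = reflectance.bands()
    alb = np.zeros_like(bands[0], dtype=float)
    for w, b in zip(ALBEDO_WEIGHTS, bands):
        alb = alb + w * b
    return alb


def shortwave_down(
    atm: AtmosphereState, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Clear-sky incoming shortwave, W m^-2: Rs = Gsc cos(theta) d_r tau_sw."""
    return constants.gsc * atm.cos_theta * atm.dr * atm.tau_sw


def longwave_down(
    eps_a: float, ta_K: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Incoming longwave from the atmosphere, W m^-2: eps_a sigma Ta^4."""
    return eps_a * constants.sigma * ta_K**4


def surface_emissivity(ndvi: np.ndarray) -> np.ndarray:
    """Broadband surface emissivity from NDVI.

    Vegetated/soil pixels (NDVI > 0) follow the logarithmic law
    eps0 = 1.009 + 0.047 ln(NDVI), floored at 0.9 to keep the emissivity
    physical as NDVI -> 0.  Water-class pixels (NDVI <= 0) get the
    standard broadband water emissivity 0.985.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    eps0 = np.full_like(ndvi, np.nan)
    veg = ndvi > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        eps0[veg] = 1.009 + 0.047 * np.log(ndvi[veg])
    eps0[veg] = np.clip(eps0[veg], EMISSIVITY_FLOOR, 1.009)
    water = np.isfinite(ndvi) & (ndvi <= 0)
    eps0[water] = WATER_EMISSIVITY
    return eps0


def longwave_up(
    eps0: np.ndarray, ts_K: np.ndarray, constants: PhysicalConstants = CONSTANTS
) -> np.ndarray:
    """Outgoing surface longwave per pixel, W m^-2: eps0 sigma Ts^4."""
    return eps0 * constants.sigma * np.asarray(ts_K, dtype=float) ** 4


def net_radiation(
    albedo: np.ndarray,
    rs_down: float,
    rl_down: float,
    rl_up: np.ndarray,
    eps0: np.ndarray,
) -> np.ndarray:
    """Net radiation per pixel, W m^-2.

    Rn = (1 - alpha) Rs_down + RL_down - RL_up - (1 - eps0) RL_down
    (the last term is the reflected fraction of the incoming longwave).
    """
    return (1.0 - albedo) * rs_down + rl_down - rl_up - (1.0 - eps0) * rl_down
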