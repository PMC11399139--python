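"""Soil heat flux, latent heat flux, evaporative fraction, and daily ET.

The chain is: G from an empirical midday G/Rn ratio; LE from the
Priestley-Taylor form LE = phi (Rn - G) Delta/(Delta + gamma);
EF = LE/(Rn - G) (identically phi Delta/(Delta + gamma)); instantaneous
ET from LE; and daily ET by the modified evaporative-fraction upscaling
ET_d = alpha EF (Rn - G)_d / lambda with alpha = 1.1 by default.

Unit conventions (the published formulation is silent or inconsistent on
these; see the package methods note):

* the surface temperature entering the G/Rn ratio is in degrees Celsius;
* lambda inside the instantaneous-ET conversion is 2.45e6 J kg^-1 so that
  3600 * LE / lambda yields mm h^-1 from LE in W m^-2;
* the daily available energy (Rn - G)_d is in MJ m^-2 day^-1 and is
  divided by lambda = 2.45 MJ kg^-1 to convert energy to water depth
  (1 MJ m^-2 / (2.45 MJ kg^-1) = 1/2.45 mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import CONSTANTS, PhysicalConstants
from .errors import DomainError
from .scene_io import SceneMeta

__all__ = [
    "UpscalingConfig",
    "soil_heat_flux",
    "latent_heat_flux",
    "instantaneous_et",
    "evaporative_fraction",
    "daylight_hours",
    "daily_available_energy",
    "daily_et",
]

#: Clip range of the G/Rn ratio.
G_RN_CLIP = (0.0, 0.5)


@dataclass(frozen=True)
class UpscalingConfig:
    """Daily-upscaling options.

    ``daylight_hours`` may be supplied directly; otherwise it is computed
    from ``latitude_deg`` and the scene day of year via the sunset-hour-
    angle formula.  ``daily_energy_mode`` selects the half-sine diurnal
    model ("half_sine") or a user-supplied daily-energy raster
    ("user_supplied").
    """

    alpha_upscale: float = CONSTANTS.alpha_upscale
    latitude_deg: float = 29.0
    daylight_hours: float | None = None
    daily_energy_mode: str = "half_sine"

    def __post_init__(self) -> None:
        if self.alpha_upscale <= 0:
            raise DomainError("alpha_upscale must be positive")
        if self.daily_energy_mode not in ("half_sine", "user_supplied"):
            raise DomainError(
                f"unknown daily_energy_mode {self.daily_energy_mode!r}"
            )


def soil_heat_flux(
    rn: np.ndarray,
    ts_K: np.ndarray,
    albedo: np.ndarray,
    ndvi: np.ndarray,
) -> np.ndarray:
    """Soil heat flux G, W m^-2, from the empirical midday G/Rn ratio.

    G/Rn = (Ts_C / alpha) (0.0038 alpha + 0.0074 alpha^2) (1 - 0.98 NDVI^4)

    with Ts_C the surface temperature in degrees Celsius.  The ratio is
    clipped to [0, 0.5]; pixels with zero albedo are set to nodata.
    """
    ts_C = np.asarray(ts_K, dtype=float) - 273.15
    alb = np.asarray(albedo, dtype=float)
    nd = np.asarray(ndvi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (ts_C / alb) * (0.0038 * alb + 0.0074 * alb**2) * (
            1.0 - 0.98 * nd**4
        )
    ratio = np.where(alb > 0, ratio, np.nan)
    ratio = np.clip(ratio, *G_RN_CLIP)
    return ratio * np.asarray(rn, dtype=float)


def latent_heat_flux(
    phi: np.ndarray,
    rn: np.ndarray,
    g: np.ndarray,
    delta_kPa_per_C: float,
    gamma_kPa_per_C: float,
) -> np.ndarray:
    """Latent heat flux LE = phi (Rn - G) Delta / (Delta + gamma), W m^-2.

    Negative available energy would produce LE < 0; those pixels are
    clipped to zero (count them upstream if a diagnostic is needed).
    """
    if delta_kPa_per_C <= 0 or gamma_kPa_per_C <= 0:
        raise DomainError("Delta and gamma must be positive")
    le = (
        np.asarray(phi, dtype=float)
        * (np.asarray(rn, dtype=float) - np.asarray(g, dtype=float))
        * delta_kPa_per_C
        / (delta_kPa_per_C + gamma_kPa_per_C)
    )
    return np.clip(le, 0.0, None)


def instantaneous_et(
    le: np.ndarray, constants: PhysicalConstants = CONSTANTS
) -> np.ndarray:
    """Instantaneous ET, mm h^-1: ET_i = 3600 LE / lambda, lambda in J kg^-1."""
    lam_J_per_kg = constants.lambda_MJ_per_kg * 1e6
    return 3600.0 * np.asarray(le, dtype=float) / lam_J_per_kg


def evaporative_fraction(
    le: np.ndarray, rn: np.ndarray, g: np.ndarray
) -> np.ndarray:
    """Evaporative fraction EF = LE / (Rn - G).

    Pixels with non-positive available energy become nodata.  By the
    Priestley-Taylor form, EF equals phi Delta/(Delta + gamma) exactly.
    """
    avail = np.asarray(rn, dtype=float) - np.asarray(g, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = np.where(avail > 0, np.asarray(le, dtype=float) / avail, np.nan)
    return ef


def daylight_hours(latitude_deg: float, doy: int) -> float:
    """Daylight length N (hours) from the sunset-hour-angle formula."""
    if not 1 <= doy <= 366:
        raise DomainError(f"day of year {doy} outside 1..366")
    if not -66.0 < latitude_deg < 66.0:
        raise DomainError("latitude outside the mid-latitude validity range")
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    lat = math.radians(latitude_deg)
    ws = math.acos(
        min(1.0, max(-1.0, -math.tan(lat) * math.tan(decl)))
    )
    return 24.0 / math.pi * ws


def daily_available_energy(
    rn: np.ndarray,
    g: np.ndarray,
    meta: SceneMeta,
    config: UpscalingConfig = UpscalingConfig(),
    user_supplied: np.ndarray | None = None,
) -> np.ndarray:
    """Daily integral of available energy (Rn - G)_d, MJ m^-2 day^-1.

    In ``half_sine`` mode instantaneous available energy is assumed to
    follow E(t) = E_peak sin(pi (t - sunrise)/N) through the daylight
    period of length N hours centred on solar noon; E_peak is recovered
    from the observed overpass value, and the analytic integral gives

        (Rn - G)_d = E_peak * 2 N * 3600 / pi * 1e-6  MJ m^-2 day^-1.

    Daily soil heat flux is taken as zero (the soil heat reservoir closes
    over a day), so the instantaneous available energy is Rn - G but the
    daily total represents net radiation alone.
    """
    if config.daily_energy_mode == "user_supplied":
        if user_supplied is None:
            raise DomainError("user_supplied mode requires a daily-energy raster")
        return np.asarray(user_supplied, dtype=float)

    n_hours = (
        config.daylight_hours
        if config.daylight_hours is not None
        else daylight_hours(config.latitude_deg, meta.doy)
    )
    sunrise = 12.0 - n_hours / 2.0
    t = meta.overpass_time
    if not sunrise < t < sunrise + n_hours:
        raise DomainError(
            f"overpass at {t:.2f} h is outside daylight "
            f"({sunrise:.2f}..{sunrise + n_hours:.2f} h)"
        )
    sine_factor = math.sin(math.pi * (t - sunrise) / n_hours)
    e_obs = np.asarray(rn, dtype=float) - np.asarray(g, dtype=float)
    e_peak = e_obs / sine_factor
    return e_peak * (2.0 * n_hours * 3600.0 / math.pi) * 1e-6


def daily_et(
    ef: np.ndarray,
    daily_energy: np.ndarray,
    config: UpscalingConfig = UpscalingConfig(),
    constants: PhysicalConstants = CONSTANTS,
) -> np.ndarray:
    """Daily ET, mm day^-1: ET_d = alpha EF (Rn - G)_d / lambda."""
    etd = (
        config.alpha_upscale
        * np.asarray(ef, dtype=float)
        * np.asarray(daily_energy, dtype=float)
        / constants.lambda_MJ_per_kg
    )
    return np.clip(etd, 0.0, None)
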