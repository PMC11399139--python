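"""Scalar solar-geometry and atmospheric terms at satellite overpass.

Everything here is a scene-level scalar: the pipeline drives shortwave and
longwave forcing from single reanalysis values and the sun geometry in the
scene metadata, not from per-pixel meteorology.  Temperatures are stored
in kelvin throughout the package; degrees Celsius appear only inside the
saturation-vapour-pressure slope (and the soil-heat-flux ratio, elsewhere),
which is where the underlying empirical fits are defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import CONSTANTS, PhysicalConstants
from .errors import DomainError

__all__ = [
    "MeteoSnapshot",
    "AtmosphereState",
    "inverse_relative_distance",
    "cos_incidence",
    "vapour_pressure_from_dewpoint",
    "precipitable_water",
    "beam_transmissivity",
    "diffuse_transmissivity",
    "broadband_transmissivity",
    "atmospheric_emissivity",
    "psychrometric_constant",
    "svp_slope",
    "atmosphere_at_overpass",
]


@dataclass(frozen=True)
class MeteoSnapshot:
    """Near-surface meteorology at overpass time.

    Actual vapour pressure ``ea_kPa`` may be given directly or derived
    from the dewpoint ``tdew_K`` (the standard reanalysis route); one of
    the two must be present.
    """

    ta_K: float
    pair_kPa: float
    ea_kPa: float | None = None
    tdew_K: float | None = None
    kt: float = 1.0  # clearness coefficient; 1.0 clean air, 0.5 very turbid

    def __post_init__(self) -> None:
        if not 240.0 <= self.ta_K <= 330.0:
            raise DomainError(f"air temperature {self.ta_K} K outside 240..330")
        if not 50.0 <= self.pair_kPa <= 110.0:
            raise DomainError(f"air pressure {self.pair_kPa} kPa outside 50..110")
        if not 0.0 < self.kt <= 1.0:
            raise DomainError(f"clearness coefficient {self.kt} outside (0, 1]")
        if self.ea_kPa is None and self.tdew_K is None:
            raise DomainError("one of ea_kPa or tdew_K must be supplied")
        if self.ea_kPa is not None and self.ea_kPa < 0:
            raise DomainError(f"vapour pressure {self.ea_kPa} kPa is negative")

    def vapour_pressure(self) -> float:
        if self.ea_kPa is not None:
            return self.ea_kPa
        assert self.tdew_K is not None
        return vapour_pressure_from_dewpoint(self.tdew_K)


@dataclass(frozen=True)
class AtmosphereState:
    """Derived scene-level atmospheric state."""

    dr: float
    cos_theta: float
    tau_b: float
    tau_d: float
    tau_sw: float
    w_mm: float
    eps_a: float
    gamma_kPa_per_C: float
    delta_kPa_per_C: float


def inverse_relative_distance(doy: int) -> float:
    """Inverse squared relative Earth-Sun distance factor d_r.

    d_r = 1 + 0.033 cos(2*pi*DOY/365); dimensionless, in [0.967, 1.033].
    """
    if not 1 <= doy <= 366:
        raise DomainError(f"day of year {doy} outside 1..366")
    return 1.0 + 0.033 * math.cos(doy * 2.0 * math.pi / 365.0)


def cos_incidence(sun_elevation_deg: float) -> float:
    """Cosine of the solar incidence angle from the MTL sun elevation.

    cos(theta) = cos(pi/2 - phi) = sin(phi) for flat terrain.  This is the
    single point where degrees become radians.
    """
    if not 0.0 < sun_elevation_deg <= 90.0:
        raise DomainError(
            f"sun elevation {sun_elevation_deg} deg not in (0, 90] (night scene?)"
        )
    return math.sin(math.radians(sun_elevation_deg))


def vapour_pressure_from_dewpoint(tdew_K: float) -> float:
    """Actual vapour pressure (kPa) from dewpoint via the Tetens formula."""
    if not 220.0 <= tdew_K <= 330.0:
        raise DomainError(f"dewpoint {tdew_K} K outside 220..330")
    td = tdew_K - 273.15
    return 0.6108 * math.exp(17.27 * td / (td + 237.3))


def precipitable_water(ea_kPa: float, pair_kPa: float) -> float:
    """Precipitable water W (mm): W = 0.14 ea Pair + 2.1."""
    if ea_kPa < 0:
        raise DomainError(f"vapour pressure {ea_kPa} kPa is negative")
    return 0.14 * ea_kPa * pair_kPa + 2.1


def beam_transmissivity(
    pair_kPa: float, kt: float, cos_theta: float, w_mm: float
) -> float:
    """Direct-beam transmissivity under clear sky.

    tau_B = 0.98 exp[-0.00146 Pair / (Kt cos(theta)) - 0.075 (W/cos(theta))^0.4]
    """
    if cos_theta <= 0:
        raise DomainError(f"cos(theta) = {cos_theta} must be positive")
    if not 0.0 < kt <= 1.0:
        raise DomainError(f"clearness coefficient {kt} outside (0, 1]")
    if w_mm <= 0:
        raise DomainError(f"precipitable water {w_mm} mm must be positive")
    return 0.98 * math.exp(
        -0.00146 * pair_kPa / (kt * cos_theta) - 0.075 * (w_mm / cos_theta) ** 0.4
    )


def diffuse_transmissivity(tau_b: float) -> float:
    """Diffuse transmissivity from the beam component.

    Piecewise linear with the branch switch at tau_B = 0.15 (the two
    branches do not meet exactly there; the small jump is part of the
    published formulation and is reproduced as printed).
    """
    if not 0.0 < tau_b < 1.0:
        raise DomainError(f"beam transmissivity {tau_b} outside (0, 1)")
    if tau_b >= 0.15:
        return 0.35 - 0.36 * tau_b
    return 0.18 + 0.82 * tau_b


def broadband_transmissivity(tau_b: float, tau_d: float) -> float:
    """Broadband shortwave transmissivity: the sum of beam and diffuse parts."""
    return tau_b + tau_d


def atmospheric_emissivity(tau_sw: float) -> float:
    """Effective atmospheric emissivity: eps_a = 0.85 (-ln tau_sw)^0.09."""
    if not 0.0 < tau_sw < 1.0:
        raise DomainError(f"broadband transmissivity {tau_sw} outside (0, 1)")
    return 0.85 * (-math.log(tau_sw)) ** 0.09


def psychrometric_constant(
    pair_kPa: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Psychrometric constant gamma = Cp P / (eps lambda), kPa degC^-1."""
    return constants.cp * pair_kPa / (constants.mw_ratio * constants.lambda_MJ_per_kg)


def svp_slope(t_K: float) -> float:
    """Slope of the saturation-vapour-pressure curve at t_K, kPa degC^-1.

    Delta = 4098 [0.6108 exp(17.27 T / (T + 237.3))] / (T + 237.3)^2,
    with T in degrees Celsius.
    """
    if not 240.0 <= t_K <= 330.0:
        raise DomainError(f"temperature {t_K} K outside 240..330")
    t = t_K - 273.15
    es = 0.6108 * math.exp(17.27 * t / (t + 237.3))
    return 4098.0 * es / (t + 237.3) ** 2


def atmosphere_at_overpass(
    meteo: MeteoSnapshot,
    doy: int,
    sun_elevation_deg: float,
    constants: PhysicalConstants = CONSTANTS,
) -> AtmosphereState:
    """Evaluate the full scalar atmosphere chain for one scene."""
    dr = inverse_relative_distance(doy)
    cos_theta = cos_incidence(sun_elevation_deg)
    ea = meteo.vapour_pressure()
    w = precipitable_water(ea, meteo.pair_kPa)
    tau_b = beam_transmissivity(meteo.pair_kPa, meteo.kt, cos_theta, w)
    tau_d = diffuse_transmissivity(tau_b)
    tau_sw = broadband_transmissivity(tau_b, tau_d)
    return AtmosphereState(
        dr=dr,
        cos_theta=cos_theta,
        tau_b=tau_b,
        tau_d=tau_d,
        tau_sw=tau_sw,
        w_mm=w,
        eps_a=atmospheric_emissivity(tau_sw),
        gamma_kPa_per_C=psychrometric_constant(meteo.pair_kPa, constants),
        delta_kPa_per_C=svp_slope(meteo.ta_K),
    )
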