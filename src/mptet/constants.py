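"""Physical constants used throughout the energy-balance pipeline.

All values are the standard ones used in remote-sensing surface energy
balance work; they are fixed and never tuned.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of physical constants.

    Attributes
    ----------
    gsc : float
        Solar constant, W m^-2.
    sigma : float
        Stefan-Boltzmann constant, W m^-2 K^-4.
    cp : float
        Specific heat of air at constant pressure, MJ kg^-1 degC^-1.
    mw_ratio : float
        Ratio of molecular weights of water vapour to dry air.
    lambda_MJ_per_kg : float
        Latent heat of vaporization, MJ kg^-1.
    phi_max : float
        Upper bound of the Priestley-Taylor coefficient (well-watered
        surface value).
    alpha_upscale : float
        Modified coefficient applied when upscaling the evaporative
        fraction to daily ET.
    """

    gsc: float = 1367.0
    sigma: float = 5.67e-8
    cp: float = 1.013e-3
    mw_ratio: float = 0.622
    lambda_MJ_per_kg: float = 2.45
    phi_max: float = 1.26
    alpha_upscale: float = 1.1


#: Module-level default instance; treat as read-only.
CONSTANTS = PhysicalConstants()
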