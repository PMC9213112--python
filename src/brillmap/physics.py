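"""Conversions between Brillouin frequency shift, elastic contrast and moduli.

The measured Brillouin frequency shift ``nu_B`` (GHz) is normalized against
the shift of water to give the dimensionless elastic contrast

    contrast = nu_B / nu_B_water - 1

and, given refractive index ``n`` and density ``rho``, relates to the
longitudinal modulus via the acoustic velocity ``v = nu_B * lambda0 / (2 n
sin(theta/2))`` as ``M' = rho * v**2``.  The longitudinal compressibility is
``kappa_L = 1 / M'`` and for an isotropic sample ``M' = K' + 4/3 G'``.

Units: shifts in GHz, wavelengths in nm, moduli in Pa, densities in kg/m^3.
The GHz*nm product is numerically metres per second, so no unit constants
appear in the formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalConfig",
    "MaterialState",
    "MechanicalReadout",
    "shift_to_contrast",
    "contrast_to_shift",
    "shift_to_longitudinal_modulus",
    "modulus_to_shift",
    "longitudinal_to_compressibility",
    "bulk_from_longitudinal",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the Brillouin setup.

    Parameters
    ----------
    wavelength_lambda0 : float
        Incident wavelength in nm.
    scattering_angle_theta : float
        Scattering angle in degrees; 180 is backscattering.
    water_shift_nuB_water : float
        Brillouin frequency shift of water in GHz, used as the contrast
        normalization reference.
    """

    wavelength_lambda0: float = 780.24
    scattering_angle_theta: float = 180.0
    water_shift_nuB_water: float = 5.066

    def __post_init__(self) -> None:
        if self.wavelength_lambda0 <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.scattering_angle_theta <= 180:
            raise ValueError("scattering angle must be in (0, 180] degrees")
        if self.water_shift_nuB_water <= 0:
            raise ValueError("water reference shift must be positive")

    @property
    def sin_half_theta(self) -> float:
        return math.sin(math.radians(self.scattering_angle_theta) / 2.0)


@dataclass(frozen=True)
class MaterialState:
    """Material parameters needed for modulus conversions.

    ``refractive_index_n`` and ``density_rho`` must be supplied per
    material; no tissue defaults are assumed.  ``shear_modulus_Gprime``
    (Pa) is optional and only used for the bulk-modulus relation.
    """

    refractive_index_n: float
    density_rho: float
    shear_modulus_Gprime: float | None = None

    def __post_init__(self) -> None:
        if self.refractive_index_n < 1:
            raise ValueError("refractive index must be >= 1")
        if self.density_rho <= 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class MechanicalReadout:
    """Bundle of mechanical quantities derived from one shift value."""

    shift_nuB: float
    contrast_nuBbar: float
    longitudinal_modulus_Mprime: float | None = None
    compressibility_kappaL: float | None = None
    bulk_modulus_Kprime: float | None = None

    def __post_init__(self) -> None:
        if (
            self.longitudinal_modulus_Mprime is not None
            and self.compressibility_kappaL is not None
        ):
            prod = self.longitudinal_modulus_Mprime * self.compressibility_kappaL
            if not math.isclose(prod, 1.0, rel_tol=1e-9):
                raise ValueError("compressibility must be the inverse of the modulus")


def shift_to_contrast(shift, config: OpticalConfig = OpticalConfig()):
    """Dimensionless elastic contrast ``shift / water_shift - 1``.

    Accepts scalars or arrays; all shifts must be strictly positive.
    """
    arr = np.asarray(shift, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("shift must be strictly positive (GHz)")
    out = arr / config.water_shift_nuB_water - 1.0
    return out if arr.ndim else float(out)


def contrast_to_shift(contrast, config: OpticalConfig = OpticalConfig()):
    """Inverse of :func:`shift_to_contrast`; contrast must exceed -1."""
    arr = np.asarray(contrast, dtype=float)
    if np.any(arr <= -1):
        raise ValueError("contrast must be > -1")
    out = (arr + 1.0) * config.water_shift_nuB_water
    return out if arr.ndim else float(out)


def shift_to_longitudinal_modulus(
    shift, material: MaterialState, config: OpticalConfig = OpticalConfig()
):
    """Longitudinal modulus M' in Pa from the shift in GHz.

    M' = rho * (shift * lambda0 / (2 n sin(theta/2)))**2 ; the GHz*nm
    product is m/s, so the parenthesis is the acoustic velocity.
    """
    if config.sin_half_theta == 0:
        raise ValueError("sin(theta/2) = 0: invalid optical configuration")
    arr = np.asarray(shift, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("shift must be strictly positive (GHz)")
    velocity = arr * config.wavelength_lambda0 / (
        2.0 * material.refractive_index_n * config.sin_half_theta
    )
    out = material.density_rho * velocity**2
    return out if arr.ndim else float(out)


def modulus_to_shift(
    Mprime, material: MaterialState, config: OpticalConfig = OpticalConfig()
):
    """Shift in GHz from the longitudinal modulus in Pa (exact inverse)."""
    if config.sin_half_theta == 0:
        raise ValueError("sin(theta/2) = 0: invalid optical configuration")
    arr = np.asarray(Mprime, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("modulus must be strictly positive (Pa)")
    velocity = np.sqrt(arr / material.density_rho)
    out = velocity * 2.0 * material.refractive_index_n * config.sin_half_theta / (
        config.wavelength_lambda0
    )
    return out if arr.ndim else float(out)


def longitudinal_to_compressibility(Mprime):
    """Longitudinal compressibility ``kappa_L = 1 / M'`` (Pa^-1)."""
    arr = np.asarray(Mprime, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("modulus must be strictly positive (Pa)")
    out = 1.0 / arr
    return out if arr.ndim else float(out)


def bulk_from_longitudinal(Mprime: float, Gprime: float) -> float:
    """Bulk modulus ``K' = M' - 4/3 G'`` for an isotropic sample."""
    if Gprime < 0:
        raise ValueError("shear modulus must be non-negative")
    Kprime = Mprime - 4.0 / 3.0 * Gprime
    if Kprime < 0:
        raise ValueError("K' would be negative: M' < 4/3 G'")
    return Kprime
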