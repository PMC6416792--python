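"""Water-vapor physics for gravimetric conductance measurements.

A leaf drying over silica gel in the dark loses water down a gradient in
water-vapor concentration.  Because the air above silica gel has a water
activity near zero, the driving force for cuticular transpiration reduces
(almost) to the saturation concentration of water vapor at leaf temperature.
This module supplies that concentration from a Magnus-type closed form of the
saturation vapor pressure, and the general two-sided driving force

    D = a_apo * C_sat(T_leaf) - a_air * C_sat(T_air)      [g m-3]

where ``a_apo`` is the water activity of the epidermal apoplast (close to 1
in a hydrated leaf) and ``a_air`` the activity of the surrounding air.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "MOLAR_MASS_WATER",
    "KELVIN_OFFSET",
    "VaporConditions",
    "saturation_vapor_pressure",
    "saturation_vapor_concentration",
    "driving_force",
]

#: Universal gas constant, J mol-1 K-1.
GAS_CONSTANT = 8.314
#: Molar mass of water, g mol-1.
MOLAR_MASS_WATER = 18.015
#: Offset between Celsius and Kelvin scales.
KELVIN_OFFSET = 273.15

# Magnus coefficients (Alduchov & Eskridge 1996 revision): within 0.4 % of
# standard psychrometric tables over -10..100 degC, well inside the spread
# between table editions.
_MAGNUS_A = 610.94   # Pa
_MAGNUS_B = 17.625
_MAGNUS_C = 243.04   # degC

_T_MIN, _T_MAX = -10.0, 100.0


class PsychroError(ValueError):
    """Raised for out-of-range temperatures or invalid vapor conditions."""


def _check_temperature(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < _T_MIN) or np.any(t > _T_MAX):
        raise PsychroError(
            f"temperature {t} degC outside validated range "
            f"[{_T_MIN}, {_T_MAX}] degC"
        )
    return t


@dataclass(frozen=True)
class VaporConditions:
    """Leaf/air temperatures (degC) and water activities for the driving force.

    ``a_apo`` is the activity at the inner side of the cuticle; ``a_air``
    that of the surrounding air (≈0 over silica gel).
    """

    t_leaf: float
    t_air: float
    a_apo: float = 1.0
    a_air: float = 0.0

    def __post_init__(self) -> None:
        _check_temperature(self.t_leaf)
        _check_temperature(self.t_air)
        for name in ("a_apo", "a_air"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise PsychroError(f"{name}={a} outside [0, 1]")


def saturation_vapor_pressure(t):
    """Saturation water-vapor pressure (Pa) at temperature ``t`` (degC).

    Magnus form ``e_sat = A exp(B t / (C + t))``; accepts scalars or arrays.
    """
    t = _check_temperature(t)
    e = _MAGNUS_A * np.exp(_MAGNUS_B * t / (_MAGNUS_C + t))
    return e if e.ndim else float(e)


def saturation_vapor_concentration(t):
    """Saturation water-vapor concentration (g m-3) at ``t`` (degC).

    Ideal-gas conversion ``C = e_sat M_w / (R T_K)``.
    """
    t = _check_temperature(t)
    c = saturation_vapor_pressure(t) * MOLAR_MASS_WATER / (
        GAS_CONSTANT * (np.asarray(t) + KELVIN_OFFSET)
    )
    c = np.asarray(c)
    return c if c.ndim else float(c)


def driving_force(vc: VaporConditions) -> float:
    """Water-vapor concentration difference (g m-3) across the cuticle.

    With ``a_air = 0`` this is exactly
    ``a_apo * saturation_vapor_concentration(t_leaf)``.

    Raises :class:`PsychroError` if the air-side term exceeds the leaf-side
    term (no outward flux; invalid for a drying experiment).
    """
    leaf = vc.a_apo * saturation_vapor_concentration(vc.t_leaf)
    air = vc.a_air * saturation_vapor_concentration(vc.t_air) if vc.a_air else 0.0
    d = leaf - air
    if d < 0:
        raise PsychroError(
            f"negative driving force ({d:.3g} g m-3): air-side vapor "
            "concentration exceeds the leaf-side term"
        )
    return d
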