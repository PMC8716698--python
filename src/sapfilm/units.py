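"""Unit conventions and conversions shared by every analysis stage.

Display units throughout the package: lengths in nm, surface tension in
mN/m, pressure in MPa, time in ps, energy in k_BT at an explicit
temperature.  Tension is a *negative* MPa value (a pulled interface);
no absolute-value inputs anywhere.

A handy identity used all over: with h in nm and P in MPa,
``h * P`` is already a surface tension in mN/m (1e-9 m * 1e6 Pa = 1e-3 N/m).
"""

from __future__ import annotations

import re

#: CODATA Boltzmann constant, J/K.
BOLTZMANN_J_PER_K = 1.380649e-23

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE_K = 298.0


class UnitConversionError(ValueError):
    """Raised for an unsupported or dimensionally inconsistent unit pair."""


# SI factors per dimension group.  k_BT is handled separately because it
# carries a temperature parameter ("k_BT@298").
_GROUPS: dict[str, dict[str, float]] = {
    "length": {"nm": 1e-9, "m": 1.0, "A": 1e-10, "Å": 1e-10},
    "tension": {"mN/m": 1e-3, "N/m": 1.0},
    "pressure": {"MPa": 1e6, "Pa": 1.0, "bar": 1e5},
    "energy": {"J": 1.0},
    "time": {"ps": 1e-12, "ns": 1e-9},
}

_KBT_RE = re.compile(r"^k_?BT@([0-9.]+)$")


def _factor(unit: str) -> tuple[str, float]:
    """Return (dimension group, factor-to-SI) for a unit string."""
    m = _KBT_RE.match(unit)
    if m:
        temperature = float(m.group(1))
        if temperature <= 0:
            raise UnitConversionError(f"non-positive temperature in unit {unit!r}")
        return "energy", BOLTZMANN_J_PER_K * temperature
    for group, table in _GROUPS.items():
        if unit in table:
            return group, table[unit]
    raise UnitConversionError(f"unsupported unit {unit!r}")


def convert_units(value, from_unit: str, to_unit: str):
    """Convert ``value`` between two units of the same dimension.

    Supported units: nm, m, A/Å, mN/m, N/m, MPa, Pa, bar, J, ps, ns and
    thermal energies written as ``"k_BT@<temperature in K>"``.

    Parameters
    ----------
    value : float or array-like
    from_unit, to_unit : str

    Raises
    ------
    UnitConversionError
        If either unit is unknown or the two units measure different
        dimensions (e.g. nm -> MPa).
    """
    g_from, f_from = _factor(from_unit)
    g_to, f_to = _factor(to_unit)
    if g_from != g_to:
        raise UnitConversionError(
            f"cannot convert {from_unit!r} ({g_from}) to {to_unit!r} ({g_to})"
        )
    return value * (f_from / f_to)


def kbt_joules(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy k_B*T in joules."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return BOLTZMANN_J_PER_K * temperature


def wrap_coordinates(positions, box_width: float):
    """Wrap lateral coordinates into the canonical cell [0, box_width).

    The lateral box is periodic and square, so any coordinate is
    equivalent to its image inside the primary cell.
    """
    import numpy as np

    if box_width <= 0:
        raise ValueError("box_width must be positive")
    return np.mod(np.asarray(positions, dtype=float), box_width)
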