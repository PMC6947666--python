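"""Pressure-unit handling.

The library computes in SI (metres, pascals, newtons).  Clinical airway
pressures are quoted in centimetres of water; the conversion constant
1 cmH2O = 98.0665 Pa is exact by definition (standard gravity times the
density convention for the unit).
"""

from __future__ import annotations

import re

from .errors import ValidationError

#: Exact definitional constant, Pa per cmH2O.
CMH2O_TO_PA = 98.0665

_TO_PA = {
    "cmH2O": CMH2O_TO_PA,
    "Pa": 1.0,
    "kPa": 1000.0,
}

#: Case-insensitive lookup of accepted unit spellings.
_ALIASES = {u.lower(): u for u in _TO_PA}

_PRESSURE_RE = re.compile(r"^\s*([-+]?[\d.]+(?:[eE][-+]?\d+)?)\s*([a-zA-Z2]*)\s*$")


def _canonical(unit: str) -> str:
    try:
        return _ALIASES[unit.lower()]
    except KeyError:
        raise ValidationError(
            f"unknown pressure unit {unit!r}; supported: {sorted(_TO_PA)}"
        ) from None


def pressure_convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between cmH2O, Pa and kPa.

    The conversion is exact up to floating-point rounding; converting a
    value to another unit and back reproduces it to machine precision.
    """
    src = _canonical(from_unit)
    dst = _canonical(to_unit)
    if src == dst:
        return float(value)
    return float(value) * _TO_PA[src] / _TO_PA[dst]


def parse_pressure(text: str, default_unit: str = "cmH2O") -> float:
    """Parse a pressure string like ``"10cmH2O"`` or ``"980.665 Pa"`` to Pa.

    A bare number is interpreted in ``default_unit``.
    """
    m = _PRESSURE_RE.match(str(text))
    if not m:
        raise ValidationError(f"cannot parse pressure {text!r}")
    value = float(m.group(1))
    unit = m.group(2) or default_unit
    return pressure_convert(value, unit, "Pa")
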