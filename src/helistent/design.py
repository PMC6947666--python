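"""Design-space construction and the pitch-window criteria.

Stents are shape-set on a cylindrical template; the template diameter
(12.7 mm here by default) is the reference for converting a prescribed
helix angle into a pitch, and the helix (centreline) diameter of the
finished stent is the template diameter plus one wire diameter.

Two criteria bound the useful pitch range for a given wire pair at a
reference transmural pressure (10 cmH2O, the level of positive-pressure
ventilation the stent must replace):

* the *maximum* pitch is the one at which the smaller wire already loses
  a target fraction (30 %) of stent cross-sectional area — any larger
  pitch gives too little radial support;
* the *minimum* pitch is the largest one at which the two candidate wire
  diameters differ by less than a tolerance (5 %) in area ratio — below
  it, wire choice no longer matters, and smaller pitches only add foreign
  material and obstruct mucus flow.

Both criteria are evaluated on the stent-only area ratio predicted by the
rod model; tissue stretch between coils is outside the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import NoFitError, NoSolutionError, SolverError, ValidationError
from .mechanics import HelixGeometry, WireMaterial, helix_angle, pitch_from_angle
from .solver import diameter_under_pressure
from .units import pressure_convert

__all__ = [
    "DesignPoint",
    "DesignTable",
    "StentSelection",
    "build_design_table",
    "max_pitch_for_target_reduction",
    "wire_insensitive_pitch",
    "select_stent",
]

#: Default shape-setting template diameter [m].
DEFAULT_TEMPLATE_D = 12.7e-3


@dataclass(frozen=True)
class DesignPoint:
    """One (wire diameter, helix angle) candidate design. SI units."""

    d_wire: float           #: wire diameter [m]
    theta: float            #: design helix angle on the template [rad]
    p0: float               #: pitch, pi * d_template * tan(theta) [m]
    d0: float               #: helix diameter, d_template + d_wire [m]
    outer_diameter: float   #: d0 + d_wire [m]
    area_ratio_at_ref: float  #: model area ratio at the reference pressure


@dataclass(frozen=True)
class DesignTable:
    """Grid of candidate designs evaluated at one reference pressure."""

    d_template: float
    rho_ref: float
    material: WireMaterial
    points: tuple[DesignPoint, ...]

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "wire_mm": pt.d_wire * 1e3,
                "angle_deg": math.degrees(pt.theta),
                "pitch_mm": pt.p0 * 1e3,
                "d0_mm": pt.d0 * 1e3,
                "outer_d_mm": pt.outer_diameter * 1e3,
                "area_ratio_at_ref": pt.area_ratio_at_ref,
                "pressure_ref_cmH2O": pressure_convert(self.rho_ref, "Pa", "cmH2O"),
            }
            for pt in self.points
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


def _geometry_for(d_template: float, d_wire: float, p0: float) -> HelixGeometry:
    return HelixGeometry(d0=d_template + d_wire, p0=p0, d_wire=d_wire)


def build_design_table(
    d_template: float,
    wire_diameters: Sequence[float],
    thetas: Sequence[float],
    rho_ref: float,
    mat: WireMaterial,
) -> DesignTable:
    """Evaluate every (wire, angle) pair of the design grid.

    Pitches come from the template diameter (``pi * d_template * tan(theta)``),
    the helix diameter is ``d_template + d_wire``, and each row carries the
    model-predicted stent area ratio under ``rho_ref``.  Angles in radians,
    lengths in metres, pressure in Pa.
    """
    if not wire_diameters or not thetas:
        raise ValidationError("wire_diameters and thetas must be non-empty")
    if rho_ref < 0.0:
        raise ValidationError(f"rho_ref must be >= 0, got {rho_ref}")
    points = []
    for d_wire in wire_diameters:
        for theta in thetas:
            p0 = pitch_from_angle(d_template, theta)
            geom = _geometry_for(d_template, d_wire, p0)
            try:
                state = diameter_under_pressure(geom, mat, rho_ref)
            except SolverError as exc:
                raise SolverError(
                    f"design point d_wire={d_wire}, theta={theta} rad failed: {exc}"
                ) from exc
            points.append(
                DesignPoint(
                    d_wire=d_wire,
                    theta=theta,
                    p0=p0,
                    d0=geom.d0,
                    outer_diameter=geom.outer_diameter,
                    area_ratio_at_ref=state.area_ratio,
                )
            )
    return DesignTable(
        d_template=d_template, rho_ref=rho_ref, material=mat, points=tuple(points)
    )


def _area_ratio_at(
    d_template: float, d_wire: float, mat: WireMaterial, rho: float, p0: float
) -> float:
    geom = _geometry_for(d_template, d_wire, p0)
    return diameter_under_pressure(geom, mat, rho).area_ratio


# Default pitch bracket for the criterion solvers, expressed as helix
# angles on the template: generous on both sides of the practical band.
# Above ~50 deg both candidate stents are already deep in collapse and the
# wire-diameter gap stops growing with pitch, so the bracket stays below.
_BRACKET_ANGLES_DEG = (5.0, 50.0)
_PITCH_XTOL = 1e-5  # 0.01 mm


def _pitch_bracket(d_template: float) -> tuple[float, float]:
    lo, hi = (pitch_from_angle(d_template, math.radians(a)) for a in _BRACKET_ANGLES_DEG)
    return lo, hi


def _check_monotone(f, lo: float, hi: float, n: int = 8) -> np.ndarray:
    """Coarse scan asserting f is monotone on [lo, hi]; returns the values."""
    xs = np.linspace(lo, hi, n)
    ys = np.array([f(x) for x in xs])
    dy = np.diff(ys)
    if not (np.all(dy >= -1e-12) or np.all(dy <= 1e-12)):
        raise SolverError(
            f"criterion function is not monotone on pitch bracket "
            f"[{lo}, {hi}]; sampled values {ys.tolist()}"
        )
    return ys


def max_pitch_for_target_reduction(
    d_template: float,
    d_wire: float,
    mat: WireMaterial,
    rho: float,
    target_area_reduction: float,
    bracket: tuple[float, float] | None = None,
) -> float:
    """Pitch at which the stent loses ``target_area_reduction`` of its area.

    The stent-only area ratio decreases with pitch (a steeper helix is
    radially softer), so the pitch giving area ratio
    ``1 - target_area_reduction`` under pressure ``rho`` is the largest
    acceptable one.  Solved by bracketed bisection at 0.01 mm tolerance
    after verifying monotonicity over the bracket.
    """
    if not 0.0 < target_area_reduction < 1.0:
        raise ValidationError(
            f"target_area_reduction must be in (0, 1), got {target_area_reduction}"
        )
    lo, hi = bracket if bracket is not None else _pitch_bracket(d_template)
    target_ratio = 1.0 - target_area_reduction

    def g(p0: float) -> float:
        return _area_ratio_at(d_template, d_wire, mat, rho, p0) - target_ratio

    ys = _check_monotone(g, lo, hi)
    if ys[0] * ys[-1] > 0.0:
        raise NoSolutionError(
            f"target area ratio {target_ratio} not attained on bracket "
            f"[{lo}, {hi}]: attained range "
            f"[{min(ys) + target_ratio}, {max(ys) + target_ratio}]"
        )
    return brentq(g, lo, hi, xtol=_PITCH_XTOL)


def wire_insensitive_pitch(
    d_template: float,
    d_wire_small: float,
    d_wire_large: float,
    mat: WireMaterial,
    rho: float,
    tol: float,
    bracket: tuple[float, float] | None = None,
) -> float:
    """Largest pitch at which the two wire diameters perform within ``tol``.

    The area-ratio gap between a thin and a thick wire grows with pitch
    and vanishes as the pitch shrinks; the returned pitch is where the gap
    equals ``tol`` (e.g. 0.05 for a 5 % difference in area ratio).
    """
    if not d_wire_small < d_wire_large:
        raise ValidationError(
            f"need d_wire_small < d_wire_large, got {d_wire_small} >= {d_wire_large}"
        )
    if not 0.0 < tol < 1.0:
        raise ValidationError(f"tol must be in (0, 1), got {tol}")
    lo, hi = bracket if bracket is not None else _pitch_bracket(d_template)

    def gap(p0: float) -> float:
        return abs(
            _area_ratio_at(d_template, d_wire_small, mat, rho, p0)
            - _area_ratio_at(d_template, d_wire_large, mat, rho, p0)
        )

    def g(p0: float) -> float:
        return gap(p0) - tol

    ys = _check_monotone(g, lo, hi)
    if ys[-1] <= 0.0:
        # Tolerance met over the whole bracket: its upper edge is the
        # largest admissible pitch.
        return hi
    if ys[0] > 0.0:
        raise NoSolutionError(
            f"area-ratio gap exceeds tol={tol} over the whole bracket "
            f"[{lo}, {hi}]: gap range [{min(ys) + tol}, {max(ys) + tol}]"
        )
    return brentq(g, lo, hi, xtol=_PITCH_XTOL)


@dataclass(frozen=True)
class StentSelection:
    """Outcome of matching available stent diameters to an airway."""

    diameter: float        #: selected helix diameter [m]
    preload_margin: float  #: diameter - trachea_d [m], >= 0
    margin_warning: bool   #: True if the margin exceeds the configured cap


def select_stent(
    available_d0: Sequence[float],
    trachea_d: float,
    margin_cap: float = 2e-3,
) -> StentSelection:
    """Pick the smallest available diameter at least the tracheal diameter.

    A diameter at or above the airway diameter guarantees the relaxed
    stent preloads against the tissue, resisting migration.  An oversize
    margin beyond ``margin_cap`` (default 2 mm) is flagged, not rejected.
    """
    if not available_d0:
        raise ValidationError("available_d0 must be non-empty")
    if trachea_d <= 0.0:
        raise ValidationError(f"trachea_d must be > 0, got {trachea_d}")
    fitting = [d for d in available_d0 if d >= trachea_d]
    if not fitting:
        raise NoFitError(
            f"no available diameter >= trachea diameter {trachea_d} "
            f"(candidates: {sorted(available_d0)})"
        )
    chosen = min(fitting)
    margin = chosen - trachea_d
    return StentSelection(
        diameter=chosen, preload_margin=margin, margin_warning=margin > margin_cap
    )
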