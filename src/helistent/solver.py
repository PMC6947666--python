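"""Equilibrium of the pressured helical stent.

The solution proceeds in two stages.

1.  *Pitch given diameter.*  For a prescribed reduced diameter ``d`` the
    deformed shape is assumed to remain a helix; its pitch minimizes the
    elastic energy.  The stationarity condition ``dE/dp = 0`` reduces to a
    quartic ``a0 + a1 p + a3 p^3 + a4 p^4 = 0`` (the quadratic coefficient
    vanishes identically), solved via the companion-matrix eigenvalue
    route; the admissible root with minimal energy is taken.

2.  *Pressure given diameter.*  Balancing internal force and moment along
    the wire (a Cosserat rod in equilibrium, frictionless contact with the
    airway wall) gives a closed-form radial contact force per unit wire
    length at the energy-minimizing pitch:

        f_x = (u_y^2 + u_z^2)/u_z * ((k_t - k_b) u_y u_z
                                      - k_t u_hat_z u_y + k_b u_hat_y u_z)

    A uniform transmural pressure ``rho`` loads each coil over a band of
    the cylinder of width ``p``; dividing that load by the coil length
    converts between pressure and line force:  f = rho * pi * d * p / c.

3.  *Diameter given pressure* inverts stage 2 with a damped Newton
    iteration started from the unloaded diameter, with a bisection
    fallback.

The body frame has x pointing at the helix axis, so a positive ``f_x`` is
the radially inward line load the stent resists; public functions return
magnitudes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InfeasibleGeometryError, SolverError, ValidationError
from .mechanics import (
    DeformedState,
    HelixGeometry,
    WireMaterial,
    coil_length,
    curvature_vector,
    elastic_energy,
    helix_angle,
)
from .units import pressure_convert

__all__ = [
    "PressureCurve",
    "equilibrium_pitch",
    "contact_line_force",
    "pressure_for_diameter",
    "diameter_under_pressure",
    "pressure_sweep",
]

logger = logging.getLogger(__name__)

# Roots with |imag| below this (relative to magnitude) count as real; the
# companion-matrix eigensolver leaves O(eps) imaginary dust on real roots.
_IMAG_TOL = 1e-9
# Energy ties below this relative gap resolve to the root nearest p0.
_TIE_TOL = 1e-12


def _quartic_coeffs(
    geom: HelixGeometry, mat: WireMaterial, d: float
) -> tuple[float, float, float, float, float]:
    """Coefficients (a0, a1, a2, a3, a4) of the pitch stationarity quartic."""
    k_b, k_t = mat.section_stiffness(geom.d_wire)
    _, uy_hat, uz_hat = geom.u_hat
    pi = math.pi
    a0 = -k_t * uz_hat * pi**4 * d**4
    a1 = 2.0 * pi**3 * d**2 * (k_t - 2.0 * k_b + k_b * uy_hat * d)
    a2 = 0.0
    a3 = 2.0 * pi * (k_b * uy_hat * d - k_t)
    a4 = k_t * uz_hat
    return a0, a1, a2, a3, a4


def _pitch_unchecked(geom: HelixGeometry, mat: WireMaterial, d: float) -> float:
    """Energy-minimizing pitch at diameter ``d``; no upper bound on d.

    Used internally so the Newton iteration may probe marginally beyond
    ``d0`` while estimating derivatives near the unloaded state.
    """
    a0, a1, a2, a3, a4 = _quartic_coeffs(geom, mat, d)
    # np.roots builds the companion matrix and takes its eigenvalues.
    roots = np.roots([a4, a3, a2, a1, a0])
    scale = np.max(np.abs(roots)) or 1.0
    real = roots[np.abs(roots.imag) <= _IMAG_TOL * scale].real
    candidates = real[real > 0.0]
    if candidates.size == 0:
        raise InfeasibleGeometryError(
            f"no positive real pitch root at d={d!r} "
            f"(geometry d0={geom.d0}, p0={geom.p0}); roots: {roots.tolist()}",
            roots=roots,
        )
    energies = np.array([elastic_energy(geom, mat, d, p) for p in candidates])
    e_min = energies.min()
    tied = candidates[energies <= e_min * (1.0 + _TIE_TOL) + _TIE_TOL]
    # Physical continuity: among energy ties prefer the branch nearest p0.
    return float(tied[np.argmin(np.abs(tied - geom.p0))])


def _validate_diameter(geom: HelixGeometry, d: float) -> None:
    if not (0.0 < d <= geom.d0):
        raise ValidationError(f"diameter must satisfy 0 < d <= d0={geom.d0}, got {d}")


def equilibrium_pitch(geom: HelixGeometry, mat: WireMaterial, d: float) -> float:
    """Pitch that minimizes elastic energy at reduced diameter ``d`` [m].

    Radial compression of a helix lengthens it: the returned pitch is
    ``>= p0`` for ``d <= d0``, equal at the unloaded diameter.
    """
    _validate_diameter(geom, d)
    return _pitch_unchecked(geom, mat, d)


def _f_x_signed(geom: HelixGeometry, mat: WireMaterial, d: float, p: float) -> float:
    """Signed radial line force at configuration (d, p); + is inward."""
    k_b, k_t = mat.section_stiffness(geom.d_wire)
    _, uy_hat, uz_hat = geom.u_hat
    _, uy, uz = curvature_vector(d, p)
    return (uy * uy + uz * uz) / uz * (
        (k_t - k_b) * uy * uz - k_t * uz_hat * uy + k_b * uy_hat * uz
    )


def _rho_signed(geom: HelixGeometry, mat: WireMaterial, d: float) -> float:
    """Signed supported pressure at diameter ``d``; + for compression."""
    p = _pitch_unchecked(geom, mat, d)
    c = coil_length(d, p)
    return _f_x_signed(geom, mat, d, p) * c / (math.pi * d * p)


def contact_line_force(geom: HelixGeometry, mat: WireMaterial, d: float) -> float:
    """Magnitude of the radial contact force per unit wire length [N/m].

    Evaluated at the energy-minimizing pitch for diameter ``d``; zero at
    the unloaded diameter and linear in the elastic modulus.
    """
    _validate_diameter(geom, d)
    p = _pitch_unchecked(geom, mat, d)
    return abs(_f_x_signed(geom, mat, d, p))


def pressure_for_diameter(geom: HelixGeometry, mat: WireMaterial, d: float) -> float:
    """Uniform external pressure that holds the stent at diameter ``d`` [Pa]."""
    _validate_diameter(geom, d)
    return abs(_rho_signed(geom, mat, d))


def _identity_state(geom: HelixGeometry) -> DeformedState:
    """The unloaded stent: exactly zero energy, force and pressure."""
    return DeformedState(
        d=geom.d0,
        p=geom.p0,
        c=geom.c0,
        u=geom.u_hat,
        energy=0.0,
        f_line=0.0,
        pressure=0.0,
        area_ratio=1.0,
    )


def _make_state(geom: HelixGeometry, mat: WireMaterial, d: float) -> DeformedState:
    if d == geom.d0:
        return _identity_state(geom)
    p = _pitch_unchecked(geom, mat, d)
    c = coil_length(d, p)
    u = curvature_vector(d, p)
    f = abs(_f_x_signed(geom, mat, d, p))
    rho = f * c / (math.pi * d * p)
    return DeformedState(
        d=d,
        p=p,
        c=c,
        u=u,
        energy=elastic_energy(geom, mat, d, p),
        f_line=f,
        pressure=rho,
        area_ratio=(d / geom.d0) ** 2,
    )


def diameter_under_pressure(
    geom: HelixGeometry,
    mat: WireMaterial,
    rho: float,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> DeformedState:
    """Equilibrium state of the stent under external pressure ``rho`` [Pa].

    Solves ``pressure_for_diameter(d) = rho`` by Newton--Raphson from
    ``d = d0`` with a central-difference derivative; if an iterate leaves
    the admissible interval or the update stalls, falls back to bracketed
    bisection (Brent) on a sub-interval of ``(0, d0]``.  Converged when
    ``|delta d| < tol`` (metres).

    Negative pressure (expansion) is rejected: the model is derived for
    radial compression only.
    """
    if rho < 0.0:
        raise ValidationError(f"negative (expansive) pressure not modelled: {rho}")
    if rho == 0.0:
        return _make_state(geom, mat, geom.d0)

    def g(d: float) -> float:
        return _rho_signed(geom, mat, d) - rho

    d0 = geom.d0
    h = 1e-8 * d0
    d = d0
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        gd = g(d)
        # One-sided step at the upper boundary keeps the probe out of the
        # strongly extrapolated d > d0 region.
        hi = min(d + h, d0 + h)
        dg = (g(hi) - g(d - h)) / (hi - (d - h))
        if dg == 0.0 or not math.isfinite(dg):
            break
        step = gd / dg
        d_new = d - step
        trace.append(d_new)
        if not (0.3 * d0 < d_new <= d0 + 1e-6 * d0):
            break
        if abs(d_new - d) < tol:
            d = min(d_new, d0)
            converged = True
            break
        d = d_new
    if not converged:
        d = _bisect_diameter(geom, mat, rho, g, trace)
    logger.debug("diameter_under_pressure: rho=%g Pa -> d=%.12g m", rho, d)
    return _make_state(geom, mat, d)


def _bisect_diameter(geom, mat, rho, g, trace) -> float:
    """Brent fallback: expand the lower bracket edge until the sign flips."""
    d0 = geom.d0
    d_lo = 0.5 * d0
    while g(d_lo) < 0.0:
        d_lo *= 0.5
        if d_lo < 0.05 * d0:
            raise SolverError(
                f"cannot bracket diameter for rho={rho} Pa "
                f"(d0={d0}, last Newton iterates {trace[-5:]})"
            )
    # g(d0) = -rho < 0, g(d_lo) >= 0: a root is guaranteed in between.
    return brentq(g, d_lo, d0, xtol=1e-12 * d0)


@dataclass(frozen=True)
class PressureCurve:
    """Ordered equilibrium states along a quasistatic pressure sweep."""

    geometry: HelixGeometry
    material: WireMaterial
    states: tuple[DeformedState, ...]

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the sweep (lengths in mm, pressure in both cmH2O and Pa)."""
        rows = [
            {
                "pressure_cmH2O": pressure_convert(s.pressure, "Pa", "cmH2O"),
                "pressure_Pa": s.pressure,
                "diameter_mm": s.d * 1e3,
                "pitch_mm": s.p * 1e3,
                "helix_angle_deg": math.degrees(helix_angle(s.d, s.p)),
                "area_ratio": s.area_ratio,
                "line_force_N_per_m": s.f_line,
                "energy_J": s.energy,
            }
            for s in self.states
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


def pressure_sweep(
    geom: HelixGeometry,
    mat: WireMaterial,
    rho_max: float,
    n_points: int,
) -> PressureCurve:
    """Equilibria at ``n_points`` equally spaced pressures in [0, rho_max].

    The first state is the unloaded identity state.  The stent stiffens
    monotonically, so the area ratio must be non-increasing along the
    sweep; a violation indicates a solver failure and aborts.
    """
    if rho_max <= 0.0:
        raise ValidationError(f"rho_max must be > 0, got {rho_max}")
    if n_points < 2:
        raise ValidationError(f"n_points must be >= 2, got {n_points}")
    states = []
    for rho in np.linspace(0.0, rho_max, n_points):
        try:
            states.append(diameter_under_pressure(geom, mat, float(rho)))
        except SolverError as exc:
            raise SolverError(f"sweep failed at rho={rho} Pa: {exc}") from exc
    ratios = [s.area_ratio for s in states]
    if any(b > a + 1e-12 for a, b in zip(ratios, ratios[1:])):
        raise SolverError(
            "area ratio is not non-increasing along the pressure sweep; "
            f"ratios={ratios}"
        )
    return PressureCurve(geometry=geom, material=mat, states=tuple(states))
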