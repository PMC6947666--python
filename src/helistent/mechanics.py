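"""Helix kinematics, wire section stiffness and elastic energy.

A helical stent is modelled as an inextensible, unshearable elastic rod
wound into a helix of (wire-centreline) diameter ``d`` and pitch ``p``.
In the body frame of the wire — z tangent to the wire, x pointing at the
helix axis — a uniform helix has the constant curvature/twist vector

    u(d, p) = [0,  2*pi^2*d / c^2,  2*pi*p / c^2],   c = sqrt(pi^2 d^2 + p^2)

where ``c`` is the wire arc length of one full coil.  The second component
is the bending rate, the third the twisting rate, both per unit arc length.
Radial compression changes ``u`` away from its shape-set value ``u_hat``;
the stored elastic energy per the linear rod model is

    E = (l/2) (u - u_hat)^T K (u - u_hat)

with ``l`` the total wire length and ``K = diag(k_b, k_b, k_t)`` the
bending/torsion section stiffness of the round wire.

All quantities are in consistent units; the package convention is SI
(metres, pascals, joules).  Every formula is algebraically homogeneous,
so any consistent unit system gives identical dimensionless outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "HelixGeometry",
    "WireMaterial",
    "DeformedState",
    "coil_length",
    "curvature_vector",
    "helix_angle",
    "pitch_from_angle",
    "section_stiffness",
    "elastic_energy",
]


def coil_length(d: float, p: float) -> float:
    """Arc length of wire in one full coil, ``sqrt(pi^2 d^2 + p^2)``.

    Degenerate limits are admitted: ``d = 0`` gives a straight wire of
    length ``p`` per "coil", ``p = 0`` a closed circle of circumference
    ``pi*d``.  Both zero, or any negative input, is rejected.
    """
    if d < 0.0 or p < 0.0:
        raise ValidationError(f"coil_length: negative input d={d}, p={p}")
    if d == 0.0 and p == 0.0:
        raise ValidationError("coil_length: d and p cannot both be zero")
    return math.hypot(math.pi * d, p)


def curvature_vector(d: float, p: float) -> np.ndarray:
    """Body-frame curvature/twist vector ``[0, 2*pi^2*d/c^2, 2*pi*p/c^2]``.

    Satisfies ``||u|| * c = 2*pi`` identically: one coil turns the frame
    through a full revolution about the helix axis.
    """
    if d <= 0.0:
        raise ValidationError(f"curvature_vector: need d > 0, got {d}")
    if p < 0.0:
        raise ValidationError(f"curvature_vector: need p >= 0, got {p}")
    c2 = (math.pi * d) ** 2 + p * p
    return np.array([0.0, 2.0 * math.pi**2 * d / c2, 2.0 * math.pi * p / c2])


def helix_angle(d: float, p: float) -> float:
    """Helix angle in radians: ``atan(p / (pi*d))``, in (0, pi/2).

    The angle between a coil and the plane normal to the helix axis.
    """
    if d <= 0.0 or p <= 0.0:
        raise ValidationError(f"helix_angle: need d, p > 0, got d={d}, p={p}")
    return math.atan2(p, math.pi * d)


def pitch_from_angle(d_ref: float, theta: float) -> float:
    """Pitch of a helix with angle ``theta`` (radians) on diameter ``d_ref``.

    Inverse of :func:`helix_angle` at fixed diameter:
    ``p = pi * d_ref * tan(theta)``.
    """
    if d_ref <= 0.0:
        raise ValidationError(f"pitch_from_angle: need d_ref > 0, got {d_ref}")
    if not 0.0 < theta < math.pi / 2.0:
        raise ValidationError(
            f"pitch_from_angle: theta must be in (0, pi/2) rad, got {theta}"
        )
    return math.pi * d_ref * math.tan(theta)


def section_stiffness(E: float, nu: float, d_wire: float) -> tuple[float, float]:
    """Bending and torsional rigidity ``(k_b, k_t)`` of a solid round wire.

    ``k_b = E*I = E*pi*r^4/4`` and ``k_t = G*J = G*pi*r^4/2`` with
    ``r = d_wire/2`` and shear modulus ``G = E / (2*(1+nu))``.  Their ratio
    ``k_t/k_b = 1/(1+nu)`` depends on the Poisson ratio only.
    """
    if E <= 0.0:
        raise ValidationError(f"section_stiffness: need E > 0, got {E}")
    if not 0.0 <= nu < 0.5:
        raise ValidationError(f"section_stiffness: need 0 <= nu < 0.5, got {nu}")
    if d_wire <= 0.0:
        raise ValidationError(f"section_stiffness: need d_wire > 0, got {d_wire}")
    r = d_wire / 2.0
    G = E / (2.0 * (1.0 + nu))
    k_b = E * math.pi * r**4 / 4.0
    k_t = G * math.pi * r**4 / 2.0
    return k_b, k_t


@dataclass(frozen=True)
class HelixGeometry:
    """Undeformed (shape-set) stent geometry.

    Parameters
    ----------
    d0 : float
        Unloaded helix diameter measured at the wire centreline [m].  The
        stent outer diameter is ``d0 + d_wire``.
    p0 : float
        Unloaded pitch — axial advance per full coil [m].
    d_wire : float
        Wire diameter [m]; must be smaller than ``d0``.
    n_coils : float
        Number of complete coils (may be fractional); default 3.
    """

    d0: float
    p0: float
    d_wire: float
    n_coils: float = 3.0

    def __post_init__(self) -> None:
        for name in ("d0", "p0", "d_wire", "n_coils"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0.0):
                raise ValidationError(f"HelixGeometry: {name} must be finite and > 0, got {v}")
        if self.d_wire >= self.d0:
            raise ValidationError(
                f"HelixGeometry: d_wire ({self.d_wire}) must be < d0 ({self.d0})"
            )

    @property
    def c0(self) -> float:
        """Unloaded single-coil wire length [m]."""
        return coil_length(self.d0, self.p0)

    @property
    def l(self) -> float:
        """Total wire length ``n_coils * c0`` [m]; constant under deformation."""
        return self.n_coils * self.c0

    @property
    def u_hat(self) -> np.ndarray:
        """Intrinsic (stress-free) curvature vector [1/m]."""
        return curvature_vector(self.d0, self.p0)

    @property
    def theta0(self) -> float:
        """Unloaded helix angle [rad]."""
        return helix_angle(self.d0, self.p0)

    @property
    def outer_diameter(self) -> float:
        """Stent outer diameter ``d0 + d_wire`` [m]."""
        return self.d0 + self.d_wire


@dataclass(frozen=True)
class WireMaterial:
    """Linear-elastic wire material.

    Nitinol stent wire is superelastic; the rod model here is linearly
    elastic, so ``E`` is an effective austenite modulus.  Defaults are
    E = 75 GPa, nu = 0.3, typical for austenitic NiTi.
    """

    E: float = 75e9
    nu: float = 0.3

    def __post_init__(self) -> None:
        if not (math.isfinite(self.E) and self.E > 0.0):
            raise ValidationError(f"WireMaterial: E must be finite and > 0, got {self.E}")
        if not 0.0 <= self.nu < 0.5:
            raise ValidationError(f"WireMaterial: need 0 <= nu < 0.5, got {self.nu}")

    @property
    def G(self) -> float:
        """Shear modulus ``E / (2*(1+nu))`` [Pa]."""
        return self.E / (2.0 * (1.0 + self.nu))

    def section_stiffness(self, d_wire: float) -> tuple[float, float]:
        """``(k_b, k_t)`` for a round wire of this material [N m^2]."""
        return section_stiffness(self.E, self.nu, d_wire)

    def stiffness_matrix(self, d_wire: float) -> np.ndarray:
        """Diagonal rod stiffness ``K = diag(k_b, k_b, k_t)`` [N m^2]."""
        k_b, k_t = self.section_stiffness(d_wire)
        return np.diag([k_b, k_b, k_t])


def elastic_energy(geom: HelixGeometry, mat: WireMaterial, d: float, p: float) -> float:
    """Elastic energy of the helix deformed to diameter ``d``, pitch ``p`` [J].

    ``(l/2) * (u - u_hat)^T K (u - u_hat)``; zero iff the configuration is
    the shape-set one, strictly positive otherwise (K is positive definite).
    """
    if d <= 0.0 or p <= 0.0:
        raise ValidationError(f"elastic_energy: need d, p > 0, got d={d}, p={p}")
    k_b, k_t = mat.section_stiffness(geom.d_wire)
    du = curvature_vector(d, p) - geom.u_hat
    return 0.5 * geom.l * (k_b * (du[0] ** 2 + du[1] ** 2) + k_t * du[2] ** 2)


@dataclass(frozen=True)
class DeformedState:
    """One equilibrium of the pressured stent.

    All fields are SI.  ``area_ratio`` is ``(d/d0)^2`` — the stent
    cross-sectional area under load over its unloaded value; the
    corresponding area reduction is ``1 - area_ratio``.
    """

    d: float            #: deformed helix diameter [m]
    p: float            #: equilibrium pitch [m]
    c: float            #: deformed single-coil wire length [m]
    u: np.ndarray = field(repr=False)  #: deformed curvature vector [1/m]
    energy: float       #: stored elastic energy [J]
    f_line: float       #: radial contact force per unit wire length [N/m]
    pressure: float     #: supported external pressure [Pa]
    area_ratio: float   #: (d/d0)^2, dimensionless

    @property
    def theta(self) -> float:
        """Deformed helix angle [rad]."""
        return helix_angle(self.d, self.p)
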