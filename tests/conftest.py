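"""Shared fixtures and independent numerical oracles.

The oracles deliberately re-derive their quantities without touching the
solver paths they are used to check:

* ``grid_pitch_oracle`` minimizes the elastic energy over a dense pitch
  grid (vectorized re-implementation of the energy quadratic form),
  followed by a bounded scalar refinement inside one grid cell — it never
  sees the stationarity quartic.
* ``virtual_work_force_oracle`` differentiates the minimized energy with
  respect to diameter: the radial line force times the wire length times
  half the diameter change must equal the energy change, so
  ``|f| = (2/l) |dE_min/dd|`` — it never sees the closed-form force.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings
from scipy.optimize import minimize_scalar

from helistent import HelixGeometry, WireMaterial, equilibrium_pitch, elastic_energy

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

TEMPLATE_MM = 12.7
PAPER_WIRES_MM = (0.38, 0.51)
PAPER_PITCHES_MM = (10.7, 14.5, 18.6, 23.0, 27.9)
PAPER_ANGLES_DEG = (15.0, 20.0, 25.0, 30.0, 35.0)
INVIVO_DIAMETERS_MM = (10.03, 11.62, 13.21, 14.80, 16.38)


def paper_geometry(wire_mm: float, pitch_mm: float) -> HelixGeometry:
    return HelixGeometry(
        d0=(TEMPLATE_MM + wire_mm) * 1e-3,
        p0=pitch_mm * 1e-3,
        d_wire=wire_mm * 1e-3,
        n_coils=3.0,
    )


@pytest.fixture(scope="session")
def default_material() -> WireMaterial:
    return WireMaterial()


@pytest.fixture(scope="session")
def paper_geometries() -> list[HelixGeometry]:
    """The ten candidate stents of the design study, SI units."""
    return [
        paper_geometry(w, p) for w in PAPER_WIRES_MM for p in PAPER_PITCHES_MM
    ]


@pytest.fixture(scope="session")
def invivo_geometry() -> HelixGeometry:
    """The deployed stent: 13.21 mm diameter, 18.6 mm pitch, 0.51 mm wire."""
    return paper_geometry(0.51, 18.6)


def grid_pitch_oracle(
    geom: HelixGeometry,
    mat: WireMaterial,
    d: float,
    step: float = 1e-6,
) -> float:
    """Energy-minimizing pitch by dense grid search plus local refinement."""
    k_b, k_t = mat.section_stiffness(geom.d_wire)
    _, uy_hat, uz_hat = geom.u_hat

    def energy(p):
        c2 = (math.pi * d) ** 2 + p * p
        uy = 2.0 * math.pi**2 * d / c2
        uz = 2.0 * math.pi * p / c2
        return 0.5 * geom.l * (k_b * (uy - uy_hat) ** 2 + k_t * (uz - uz_hat) ** 2)

    grid = np.arange(0.5 * geom.p0, 3.0 * geom.p0, step)
    i = int(np.argmin(energy(grid)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(energy, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-13})
    return float(res.x)


def virtual_work_force_oracle(
    geom: HelixGeometry, mat: WireMaterial, d: float
) -> float:
    """Line-force magnitude from a central difference of the minimized energy."""
    h = 1e-7 * geom.d0

    def e_min(x):
        return elastic_energy(geom, mat, x, equilibrium_pitch(geom, mat, x))

    return (2.0 / geom.l) * abs((e_min(d + h) - e_min(d - h)) / (2.0 * h))
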