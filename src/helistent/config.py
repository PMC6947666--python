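"""Run configuration and seeded fixture generation.

Configuration is a flat YAML key-value file mirroring the CLI flags;
flags override file values.  All user-facing lengths are millimetres and
pressures carry a unit tag; conversion to SI happens here, once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .mechanics import HelixGeometry, WireMaterial, pitch_from_angle
from .units import parse_pressure, pressure_convert

__all__ = ["RunConfig", "load_config", "fixture_generator"]


@dataclass
class RunConfig:
    """Resolved inputs of one run, in user units (mm, degrees, cmH2O tags).

    Exactly one of ``pitch_mm`` / ``angle_deg`` must be given; the other
    is derived from the template diameter.
    """

    template_mm: float = 12.7
    wire_mm: float = 0.51
    pitch_mm: float | None = None
    angle_deg: float | None = None
    coils: float = 3.0
    E_GPa: float = 75.0
    nu: float = 0.3
    pressure: str = "10 cmH2O"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.pitch_mm is None) == (self.angle_deg is None):
            raise ValidationError(
                "exactly one of pitch_mm / angle_deg must be specified"
            )
        for name in ("template_mm", "wire_mm", "coils", "E_GPa"):
            if getattr(self, name) <= 0.0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def resolved_pitch_mm(self) -> float:
        if self.pitch_mm is not None:
            return self.pitch_mm
        theta = math.radians(self.angle_deg)
        return pitch_from_angle(self.template_mm, theta)

    def geometry(self) -> HelixGeometry:
        return HelixGeometry(
            d0=(self.template_mm + self.wire_mm) * 1e-3,
            p0=self.resolved_pitch_mm * 1e-3,
            d_wire=self.wire_mm * 1e-3,
            n_coils=self.coils,
        )

    def material(self) -> WireMaterial:
        return WireMaterial(E=self.E_GPa * 1e9, nu=self.nu)

    def pressure_pa(self) -> float:
        return parse_pressure(self.pressure)

    def as_dict(self) -> dict:
        """Fully resolved configuration, embedded in every output artifact."""
        out = asdict(self)
        out["resolved_pitch_mm"] = self.resolved_pitch_mm
        out["pressure_Pa"] = self.pressure_pa()
        out["pressure_cmH2O"] = pressure_convert(self.pressure_pa(), "Pa", "cmH2O")
        return out


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML key-value config file; keyword arguments override it."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} must be a key-value mapping")
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def fixture_generator(
    seed: int, n: int
) -> list[tuple[HelixGeometry, WireMaterial, float]]:
    """Deterministic admissible random test cases.

    Samples ``n`` (geometry, material, pressure-in-Pa) triples spanning
    the realistic airway-stent envelope: wires 0.2--1.0 mm, helix angles
    10--40 degrees, template diameters 8--20 mm, moduli 40--83 GPa,
    pressures up to 20 cmH2O.  The same seed reproduces the same list.
    """
    if n <= 0:
        raise ValidationError(f"n must be > 0, got {n}")
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        d_wire = rng.uniform(0.2e-3, 1.0e-3)
        theta = math.radians(rng.uniform(10.0, 40.0))
        d_template = rng.uniform(8e-3, 20e-3)
        E = rng.uniform(40e9, 83e9)
        rho = rng.uniform(0.0, 20.0) * 98.0665
        geom = HelixGeometry(
            d0=d_template + d_wire,
            p0=pitch_from_angle(d_template, theta),
            d_wire=d_wire,
        )
        cases.append((geom, WireMaterial(E=E, nu=0.3), rho))
    return cases
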