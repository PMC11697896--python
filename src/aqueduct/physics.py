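"""Closed-form laminar-flow hydraulics for the cerebral aqueduct.

The aqueduct is treated as a quasi-steady Poiseuille conduit: each short
element of length ``ΔL`` and lumen diameter ``D`` contributes a hydraulic
resistance ``R = 128 µ ΔL / (π D⁴)`` and the pressure drop across a segment
is ``ΔP = R · Q``.  The Womersley and Reynolds numbers quantify how well the
quasi-steady, laminar assumptions hold (Womersley < 5, Reynolds ≪ 2000 in
healthy adults).

Unit conventions
----------------
Geometry is carried in millimetres, flow in mm³/s and viscosity in mPa·s, so
element resistances come out directly in mPa·s/mm³ — the unit the morphology
and pressure layers report.  The dimensionless numbers are evaluated in SI
internally.  ΔP is reported in Pa (1 mPa·s/mm³ × 1 mm³/s = 1 mPa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FluidConstants",
    "ElementGeometry",
    "HydraulicScalars",
    "element_resistance",
    "womersley_number",
    "reynolds_number",
    "pressure_difference",
    "pa_to_mmhg",
    "MMHG_PER_PA",
]

#: One mmHg expressed in Pa.
MMHG_PER_PA = 1.0 / 133.322


@dataclass(frozen=True)
class FluidConstants:
    """Physical constants of CSF.

    Parameters
    ----------
    mu : float
        Dynamic viscosity in mPa·s.  Default 0.71 mPa·s (water at 36 °C).
    rho : float
        Density in kg/m³.  Default 1000 kg/m³.
    """

    mu: float = 0.71
    rho: float = 1000.0

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"viscosity must be positive, got {self.mu}")
        if not self.rho > 0:
            raise ValueError(f"density must be positive, got {self.rho}")


@dataclass(frozen=True)
class ElementGeometry:
    """One finite element of the aqueduct centerline.

    Attributes
    ----------
    length : float
        Arc length ΔL of the element, mm.
    diameter : float
        Local lumen diameter D, mm.
    tangent_angle : float
        Direction of the local centerline tangent versus the image x-axis,
        degrees.
    """

    length: float
    diameter: float
    tangent_angle: float = 0.0

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"element length must be positive, got {self.length}")
        if not self.diameter > 0:
            raise ValueError(f"element diameter must be positive, got {self.diameter}")


@dataclass(frozen=True)
class HydraulicScalars:
    """Bundle of the scalar hydraulic descriptors of a conduit."""

    resistance: float  # mPa·s/mm³
    womersley: float  # dimensionless
    reynolds: float  # dimensionless
    delta_p: float  # Pa

    def __post_init__(self) -> None:
        if self.resistance < 0 or self.womersley < 0 or self.reynolds < 0:
            raise ValueError("resistance, Womersley and Reynolds must be >= 0")


def element_resistance(elem: ElementGeometry, const: FluidConstants = FluidConstants()) -> float:
    """Poiseuille resistance of one element, ``128 µ ΔL / (π D⁴)``.

    With µ in mPa·s and lengths in mm the result is in mPa·s/mm³.
    """
    return 128.0 * const.mu * elem.length / (math.pi * elem.diameter**4)


def womersley_number(
    diameter: float, cardiac_period: float, const: FluidConstants = FluidConstants()
) -> float:
    """Womersley number ``(D/2)·sqrt(ω ρ / µ)`` with ω = 2π / cardiac period.

    Parameters are diameter in mm, cardiac period in s; evaluation is in SI.
    """
    if diameter < 0:
        raise ValueError(f"diameter must be non-negative, got {diameter}")
    if not cardiac_period > 0:
        raise ValueError(f"cardiac period must be positive, got {cardiac_period}")
    omega = 2.0 * math.pi / cardiac_period  # rad/s
    mu_si = const.mu * 1e-3  # Pa·s
    radius_si = diameter * 1e-3 / 2.0  # m
    return radius_si * math.sqrt(omega * const.rho / mu_si)


def reynolds_number(
    flow: float, diameter: float, const: FluidConstants = FluidConstants()
) -> float:
    """Reynolds number ``ρ v D / µ`` with v the mean cross-sectional velocity.

    The velocity is taken as ``v = Q / (π D²/4)`` so ``Re = 4 ρ Q / (π µ D)``.
    Flow in mm³/s, diameter in mm; evaluation is in SI.
    """
    if flow < 0:
        raise ValueError(f"flow must be non-negative, got {flow}")
    if not diameter > 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    q_si = flow * 1e-9  # m³/s
    d_si = diameter * 1e-3  # m
    mu_si = const.mu * 1e-3  # Pa·s
    return 4.0 * const.rho * q_si / (math.pi * mu_si * d_si)


def pressure_difference(resistance: float, flow: float) -> float:
    """Trans-conduit pressure difference ``ΔP = R · Q`` in Pa.

    ``resistance`` in mPa·s/mm³ and ``flow`` in mm³/s give ΔP in mPa; the
    result is divided by 1000 to report Pa.  The sign of ΔP follows the sign
    of the flow.
    """
    if resistance < 0:
        raise ValueError(f"resistance must be non-negative, got {resistance}")
    return resistance * flow / 1000.0


def pa_to_mmhg(p: float) -> float:
    """Convert a pressure from Pa to mmHg (1 mmHg = 133.322 Pa)."""
    return p * MMHG_PER_PA
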