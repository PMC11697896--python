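"""Trans-aqueductal pressure differences from resistance and flow.

Multiplying the aqueduct's hydraulic resistance by the cardiac- and
breath-driven peak flow rates gives the corresponding pressure differences
(ΔP = R·Q, reported in Pa and mmHg), their peak-to-peak sums, the
breath-to-cardiac ratio, and the cumulative ΔP profile along the aqueduct
at a given flow — the pressure "gradient curve".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow import FlowMetrics
from .morphology import ResistanceProfile
from .physics import pa_to_mmhg, pressure_difference

__all__ = ["PressureMetrics", "PressureGradientCurve", "compute_pressure_metrics", "pressure_gradient_curve"]


@dataclass
class PressureMetrics:
    """Cardiac- and breath-driven pressure differences (magnitudes, Pa)."""

    dPc_plus: float
    dPc_minus: float
    dPb_plus: float
    dPb_minus: float

    @property
    def dPc(self) -> float:
        return 0.5 * (self.dPc_plus + self.dPc_minus)

    @property
    def dPb(self) -> float:
        return 0.5 * (self.dPb_plus + self.dPb_minus)

    @property
    def p2p_cardiac(self) -> float:
        """Peak-to-peak cardiac-driven ΔP, Pa."""
        return self.dPc_plus + self.dPc_minus

    @property
    def p2p_breath(self) -> float:
        """Peak-to-peak breath-driven ΔP, Pa."""
        return self.dPb_plus + self.dPb_minus

    @property
    def p2p_cardiac_mmhg(self) -> float:
        return pa_to_mmhg(self.p2p_cardiac)

    @property
    def p2p_breath_mmhg(self) -> float:
        return pa_to_mmhg(self.p2p_breath)

    @property
    def ratio_b_over_c(self) -> float:
        """Breath-driven ΔP as a percentage of the cardiac-driven ΔP."""
        return 100.0 * self.dPb / self.dPc if self.dPc != 0 else float("nan")


@dataclass
class PressureGradientCurve:
    """Cumulative ΔP versus arc length at a fixed flow rate."""

    arclength: np.ndarray  # element end positions, mm
    delta_p: np.ndarray  # cumulative ΔP, Pa

    def __post_init__(self) -> None:
        self.arclength = np.asarray(self.arclength, dtype=float)
        self.delta_p = np.asarray(self.delta_p, dtype=float)
        if self.arclength.shape != self.delta_p.shape:
            raise ValueError("arclength and delta_p must have equal length")


def compute_pressure_metrics(R: float, fm: FlowMetrics) -> PressureMetrics:
    """ΔP = R·Q for each directional cardiac/breath peak flow.

    ``R`` in mPa·s/mm³ and flows in mm³/s give ΔP in Pa.
    """
    if R < 0:
        raise ValueError("resistance must be non-negative")
    return PressureMetrics(
        dPc_plus=pressure_difference(R, fm.Qc_plus),
        dPc_minus=pressure_difference(R, fm.Qc_minus),
        dPb_plus=pressure_difference(R, fm.Qb_plus),
        dPb_minus=pressure_difference(R, fm.Qb_minus),
    )


def pressure_gradient_curve(profile: ResistanceProfile, Q: float) -> PressureGradientCurve:
    """Cumulative ΔP along the aqueduct at flow ``Q`` (mm³/s).

    At each element boundary the curve equals the cumulative resistance up
    to that point times the flow; the final value is the trans-aqueductal
    ΔP at that flow.
    """
    if Q < 0:
        raise ValueError("flow must be non-negative")
    ends = np.cumsum([e.length for e in profile.elements])
    dp = profile.cumulative_r * Q / 1000.0
    return PressureGradientCurve(ends, dp)
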