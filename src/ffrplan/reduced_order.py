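"""Flow-dependent epicardial resistance model ``R(Q) = R_in + R_sl * Q``.

Each vessel segment (one per lesion, one per healthy stretch) is summarised
by the intercept and slope of its resistance-flow relationship.  The
coefficients are calibrated from two fine-grid oracle solutions of the whole
vessel: the hyperemic boundary condition and a second one with the
microvascular resistance lowered by 40%.  With flows ``Q`` and ``Q*`` and
segment resistances ``R = dP/Q`` and ``R*``,

    R_sl = (R* - R) / (Q* - Q),    R_in = R - R_sl * Q.

If the achieved flow difference ``Q* - Q`` is too small for a stable fit the
coefficients fall back to the analytic 1D law parameterised by lumen area,
viscosity and density: ``R_in`` is the Poiseuille integral over the extent
and ``R_sl`` the expansion-loss coefficient ``S``.

Assembling the calibrated segments in series yields a scalar quadratic in the
vessel flow whose positive root is closed-form, which is what makes re-solving
after a virtual geometry change effectively instantaneous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import LesionSegment, VesselGeometry, segment_vessel
from .hemodynamics import (
    DEFAULT_FLUID,
    BoundaryCondition,
    FluidProperties,
    HemodynamicSolution,
    HemodynamicsError,
    dp_between,
    law_coefficients,
    oracle_solve,
    segment_dp,
)

__all__ = [
    "ReducedOrderSegment",
    "segment_resistance",
    "calibrate",
    "calibrate_vessel",
    "assemble_network",
    "FLOW_TOL_ML_S",
    "LOW_RESISTANCE_FACTOR",
]

FLOW_TOL_ML_S = 0.05        # minimal usable Q* - Q for the two-point fit
LOW_RESISTANCE_FACTOR = 0.6  # second calibration condition: 40% lower r_micro


@dataclass(frozen=True)
class ReducedOrderSegment:
    """Calibrated ``(R_in, R_sl)`` pair for one vessel extent.

    ``source`` records whether the coefficients came from the two-point CFD
    calibration or from the analytic 1D fallback; the calibration flows and
    resistances are kept for reporting.
    """

    extent: tuple[float, float]
    r_in: float                # mmHg s/mL
    r_sl: float                # mmHg s^2/mL^2
    source: str                # "calibrated" | "fallback"
    q: float | None = None
    q_star: float | None = None
    r: float | None = None
    r_star: float | None = None

    def __post_init__(self) -> None:
        if self.r_in < 0 or self.r_sl < 0:
            raise ValueError("r_in and r_sl must be non-negative")
        if self.source not in ("calibrated", "fallback"):
            raise ValueError("source must be 'calibrated' or 'fallback'")

    def resistance(self, q: float) -> float:
        return self.r_in + self.r_sl * q

    def dp(self, q: float) -> float:
        return self.r_in * q + self.r_sl * q * abs(q)

    def to_json_dict(self) -> dict:
        return {
            "extent_mm": list(self.extent), "r_in": self.r_in,
            "r_sl": self.r_sl, "source": self.source, "Q": self.q,
            "Q_star": self.q_star, "R": self.r, "R_star": self.r_star,
        }


def segment_resistance(geom: VesselGeometry,
                       extent: tuple[float, float],
                       q: float,
                       fluid: FluidProperties = DEFAULT_FLUID) -> float:
    """Resistance ``dP(Q)/Q`` of the extent at flow ``q`` (mL/s), from the law."""
    if q <= 0:
        raise ValueError("resistance is undefined for q <= 0")
    return segment_dp(geom, extent, q, fluid) / q


def _fit_segment(extent: tuple[float, float],
                 sol: HemodynamicSolution,
                 sol_star: HemodynamicSolution,
                 geom: VesselGeometry,
                 fluid: FluidProperties,
                 flow_tol: float) -> ReducedOrderSegment:
    q, q_star = sol.q, sol_star.q
    if q_star <= q:
        raise HemodynamicsError(
            f"calibration produced Q* = {q_star:.6g} <= Q = {q:.6g} mL/s; "
            "lowering the microvascular resistance must raise flow")
    r = dp_between(sol, *extent) / q
    r_star = dp_between(sol_star, *extent) / q_star
    if q_star - q < flow_tol:
        rv, s_coef = law_coefficients(geom, extent, fluid)
        return ReducedOrderSegment(extent, rv, s_coef, "fallback",
                                   q=q, q_star=q_star, r=r, r_star=r_star)
    r_sl = (r_star - r) / (q_star - q)
    r_in = r - r_sl * q
    # float noise on near-lossless segments can push a coefficient epsilon
    # below zero; clamp without disturbing genuine values
    return ReducedOrderSegment(extent, max(r_in, 0.0), max(r_sl, 0.0),
                               "calibrated", q=q, q_star=q_star, r=r, r_star=r_star)


def calibrate(geom: VesselGeometry,
              extent: tuple[float, float],
              bc: BoundaryCondition,
              fluid: FluidProperties = DEFAULT_FLUID,
              flow_tol: float = FLOW_TOL_ML_S) -> ReducedOrderSegment:
    """Calibrate one extent from two whole-vessel oracle solutions.

    Solves the vessel under ``bc`` and under ``bc`` with ``r_micro`` reduced
    by 40%, then fits the two-point resistance-flow line for the extent (or
    falls back to the analytic coefficients when ``Q* - Q < flow_tol``).
    """
    if flow_tol <= 0:
        raise ValueError("flow_tol must be positive")
    sol = oracle_solve(geom, bc, fluid)
    bc_star = BoundaryCondition(bc.pa, bc.pv, LOW_RESISTANCE_FACTOR * bc.r_micro)
    sol_star = oracle_solve(geom, bc_star, fluid)
    return _fit_segment(extent, sol, sol_star, geom, fluid, flow_tol)


def calibrate_vessel(geom: VesselGeometry,
                     lesions: Sequence[LesionSegment],
                     bc: BoundaryCondition,
                     fluid: FluidProperties = DEFAULT_FLUID,
                     flow_tol: float = FLOW_TOL_ML_S) -> list[ReducedOrderSegment]:
    """Calibrate every segment of the lesion/healthy tiling of the vessel.

    The two oracle solutions are shared across all segments, so the cost is
    independent of the segment count.
    """
    extents = segment_vessel(geom, lesions)
    sol = oracle_solve(geom, bc, fluid)
    bc_star = BoundaryCondition(bc.pa, bc.pv, LOW_RESISTANCE_FACTOR * bc.r_micro)
    sol_star = oracle_solve(geom, bc_star, fluid)
    return [_fit_segment(ext, sol, sol_star, geom, fluid, flow_tol)
            for ext in extents]


def assemble_network(segments: Sequence[ReducedOrderSegment],
                     bc: BoundaryCondition,
                     geom: VesselGeometry | None = None) -> HemodynamicSolution:
    """Series solution of calibrated segments plus the microvascular bed.

    Solves ``pa - pv = sum_i (R_in,i Q + R_sl,i Q^2) + r_micro Q`` for the
    positive root in closed form, then lays down the per-segment drops
    cumulatively.  The pressure profile is piecewise linear between segment
    boundaries; passing ``geom`` samples it onto the geometry grid.
    """
    if not segments:
        raise ValueError("need at least one segment")
    segs = sorted(segments, key=lambda sg: sg.extent[0])
    for a, b in zip(segs[:-1], segs[1:]):
        if abs(a.extent[1] - b.extent[0]) > 1e-6:
            raise ValueError("segments must tile the vessel without gaps/overlap")
    a_coef = sum(sg.r_sl for sg in segs)
    b_coef = sum(sg.r_in for sg in segs) + bc.r_micro
    drive = bc.pa - bc.pv
    # stable form of the positive quadratic root (no cancellation as a -> 0)
    disc = b_coef * b_coef + 4.0 * a_coef * drive
    q = 2.0 * drive / (b_coef + math.sqrt(disc))
    if not q > 0:
        raise HemodynamicsError("network has no positive flow root")
    bounds = np.array([segs[0].extent[0]] + [sg.extent[1] for sg in segs])
    p_bounds = np.empty(bounds.size)
    p_bounds[0] = bc.pa
    for i, sg in enumerate(segs):
        p_bounds[i + 1] = p_bounds[i] - sg.dp(q)
    if geom is not None:
        s_out = geom.s
        p_out = np.interp(s_out, bounds, p_bounds)
    else:
        s_out, p_out = bounds, p_bounds
    return HemodynamicSolution(s=s_out, q=float(q), p=p_out,
                               ffr=p_out / bc.pa, pa=bc.pa)
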