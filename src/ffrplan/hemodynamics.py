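"""Steady hyperemic pressure/flow solution of a stenosed conduit.

The epicardial pressure drop over any extent is modelled by the classical
viscous + post-stenotic expansion-loss law

    dP(Q) = R_v * Q + S * Q * |Q|

where ``R_v = integral 8 pi mu / A(s)^2 ds`` is the Poiseuille resistance of
the sampled lumen (``A = pi r^2``) and ``S = (Kt rho / 2) (1/A_min -
1/A_out)^2`` is the empirical expansion (separation) loss of a narrowing with
throat area ``A_min`` recovering to ``A_out``; ``Kt = 1.52``.  The law is
linear-plus-quadratic in flow, which is exactly the structure the
flow-dependent resistance model in :mod:`ffrplan.reduced_order` assumes.

Internally everything is SI; the public interface uses mmHg, mL/s and mm
(1 mmHg = 133.322 Pa).

The module's :func:`oracle_solve` is the project's ground truth: it evaluates
the law on a fine uniform grid (default 0.05 mm), locates every narrowing of
the profile automatically, and solves the vessel + microvascular series
system for the hyperemic operating point by bracketed root finding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .geometry import VesselGeometry, auto_reference, resample, _runs

__all__ = [
    "FluidProperties",
    "BoundaryCondition",
    "HemodynamicSolution",
    "HemodynamicsError",
    "DEFAULT_FLUID",
    "segment_dp",
    "law_coefficients",
    "oracle_solve",
    "ffr_at",
    "dp_between",
]

MMHG_PA = 133.322          # Pa per mmHg, fixed conversion
KT = 1.52                  # empirical expansion-loss coefficient
ORACLE_DS_MM = 0.05        # fine-grid spacing of the brute-force oracle
SITE_PCT = 0.5             # minimal % narrowing treated as an expansion site
Q_BRACKET = (1e-6, 50.0)   # physiologic flow bracket, mL/s

# resistance: Pa*s/m^3 -> mmHg*s/mL ; quadratic coefficient: Pa*s^2/m^6 -> mmHg*s^2/mL^2
_R_SI_TO_EXT = 1e-6 / MMHG_PA
_S_SI_TO_EXT = 1e-12 / MMHG_PA


class HemodynamicsError(RuntimeError):
    """Solver or model-evaluation failure."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood: dynamic viscosity (Pa s) and density (kg/m^3)."""

    mu: float = 0.0035
    rho: float = 1050.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("viscosity and density must be positive")


DEFAULT_FLUID = FluidProperties()


@dataclass(frozen=True)
class BoundaryCondition:
    """Aortic/venous pressures (mmHg) and microvascular resistance (mmHg s/mL)."""

    pa: float
    pv: float
    r_micro: float

    def __post_init__(self) -> None:
        if not self.pa > self.pv >= 0:
            raise ValueError("require pa > pv >= 0")
        if self.r_micro <= 0:
            raise ValueError("r_micro must be positive")


@dataclass(frozen=True, eq=False)
class HemodynamicSolution:
    """Flow rate plus pressure/FFR profiles at every geometry sample."""

    s: np.ndarray      # mm
    q: float           # mL/s
    p: np.ndarray      # mmHg
    ffr: np.ndarray    # p / pa
    pa: float          # mmHg

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", np.asarray(self.s, dtype=float))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        object.__setattr__(self, "ffr", np.asarray(self.ffr, dtype=float))

    @property
    def ffr_distal(self) -> float:
        return float(self.ffr[-1])

    def to_json_dict(self) -> dict:
        return {
            "q_ml_s": self.q,
            "samples": [
                {"s_mm": float(s), "p_mmHg": float(p), "ffr": float(f)}
                for s, p, f in zip(self.s, self.p, self.ffr)
            ],
        }


# ---------------------------------------------------------------------------
# segment pressure-drop law

def _clip_profile(geom: VesselGeometry, extent: tuple[float, float]):
    """Sample arrays over ``extent`` with interpolated endpoint values."""
    start, end = extent
    if end <= start:
        raise HemodynamicsError("extent must have end > start")
    if start < geom.s[0] - 1e-9 or end > geom.s[-1] + 1e-9:
        raise HemodynamicsError("extent outside vessel")
    inner = (geom.s > start) & (geom.s < end)
    s = np.r_[start, geom.s[inner], end]
    r = np.r_[geom.radius_at(start), geom.r[inner], geom.radius_at(end)]
    return s, r


def law_coefficients(geom: VesselGeometry,
                     extent: tuple[float, float],
                     fluid: FluidProperties = DEFAULT_FLUID,
                     ) -> tuple[float, float]:
    """(R_v, S) of the pressure-drop law over ``extent``, external units.

    ``R_v`` (mmHg s/mL) is the trapezoid-rule Poiseuille integral; ``S``
    (mmHg s^2/mL^2) uses the minimal area in the extent and the lumen area at
    the distal end of the extent as the recovery area.  For a non-narrowed
    (monotonically tapering or uniform) extent the throat sits at the distal
    end, so S is exactly zero and the law reduces to Poiseuille.
    """
    s_mm, r_mm = _clip_profile(geom, extent)
    if np.any(r_mm <= 0):
        raise HemodynamicsError("non-positive radius in extent")
    s_m = s_mm * 1e-3
    area = np.pi * (r_mm * 1e-3) ** 2
    rv_si = np.trapezoid(8.0 * np.pi * fluid.mu / area ** 2, s_m)
    a_min = float(area.min())
    a_out = float(area[-1])
    s_si = 0.5 * KT * fluid.rho * max(0.0, 1.0 / a_min - 1.0 / a_out) ** 2
    return rv_si * _R_SI_TO_EXT, s_si * _S_SI_TO_EXT


def segment_dp(geom: VesselGeometry,
               extent: tuple[float, float],
               q: float,
               fluid: FluidProperties = DEFAULT_FLUID) -> float:
    """Pressure drop (mmHg) over ``extent`` at flow ``q`` (mL/s).

    Evaluates ``R_v q + S q |q|``; exactly zero at ``q = 0`` and non-negative
    for ``q >= 0``.
    """
    rv, s_coef = law_coefficients(geom, extent, fluid)
    return rv * q + s_coef * q * abs(q)


# ---------------------------------------------------------------------------
# fine-grid vessel law and oracle solve

class VesselLaw:
    """Whole-vessel pressure-drop law precomputed on the geometry's grid.

    The viscous resistance is accumulated sample-by-sample; every narrowing of
    the profile exceeding ``site_pct`` percent (found against the automatic
    healthy reference) contributes one expansion-loss term whose irreversible
    drop is ramped linearly from the throat to the distal shoulder, so the
    pressure profile is non-increasing and the step sits at the lesion.
    """

    def __init__(self, geom: VesselGeometry,
                 fluid: FluidProperties = DEFAULT_FLUID,
                 site_pct: float = SITE_PCT) -> None:
        self.geom = geom
        s_m = geom.s * 1e-3
        area = np.pi * (geom.r * 1e-3) ** 2
        rv_cum_si = cumulative_trapezoid(8.0 * np.pi * fluid.mu / area ** 2,
                                         s_m, initial=0.0)
        self.rv_cum = rv_cum_si * _R_SI_TO_EXT      # mmHg s/mL at each sample
        ref = auto_reference(geom)
        narrow = 100.0 * (1.0 - geom.r / ref)
        from .geometry import EDGE_PCT
        qc = np.zeros_like(geom.s)
        sites: list[list[int]] = []
        for c0, c1 in _runs(narrow > site_pct):
            # expand to the healthy shoulders: recovery completes at the
            # full reference lumen, not at the site-threshold crossing
            i0, i1 = c0, c1
            while i0 > 0 and narrow[i0 - 1] > EDGE_PCT:
                i0 -= 1
            while i1 < geom.s.size - 1 and narrow[i1 + 1] > EDGE_PCT:
                i1 += 1
            if sites and i0 <= sites[-1][1]:
                sites[-1][1] = max(sites[-1][1], i1)
            else:
                sites.append([i0, i1])
        for i0, i1 in sites:
            sl = slice(i0, i1 + 1)
            k = i0 + int(np.argmin(area[sl]))
            j_out = min(i1 + 1, geom.s.size - 1)
            a_min = float(area[k])
            a_out = float(area[j_out])
            s_si = 0.5 * KT * fluid.rho * max(0.0, 1.0 / a_min - 1.0 / a_out) ** 2
            s_coef = s_si * _S_SI_TO_EXT            # mmHg s^2/mL^2
            if s_coef == 0.0:
                continue
            span = geom.s[j_out] - geom.s[k]
            if span > 0:
                ramp = np.clip((geom.s - geom.s[k]) / span, 0.0, 1.0)
            else:
                ramp = (geom.s >= geom.s[k]).astype(float)
            qc += s_coef * ramp
        self.qc_cum = qc

    @property
    def rv_total(self) -> float:
        return float(self.rv_cum[-1])

    @property
    def s_total(self) -> float:
        return float(self.qc_cum[-1])

    def dp_total(self, q: float) -> float:
        return self.rv_total * q + self.s_total * q * abs(q)

    def pressures(self, pa: float, q: float) -> np.ndarray:
        return pa - self.rv_cum * q - self.qc_cum * q * abs(q)


def oracle_solve(geom: VesselGeometry,
                 bc: BoundaryCondition,
                 fluid: FluidProperties = DEFAULT_FLUID,
                 ds: float = ORACLE_DS_MM) -> HemodynamicSolution:
    """Brute-force fine-grid solution of the vessel + microvascular system.

    Resamples the geometry at spacing ``ds``, builds the whole-vessel law and
    finds the flow with ``pa - pv = dP_epicardial(Q) + r_micro Q`` by Brent
    root finding on a physiologic bracket.  Raises
    :class:`HemodynamicsError` with a diagnostic if the bracket does not
    contain a root.
    """
    g = resample(geom, ds)
    law = VesselLaw(g, fluid)
    drive = bc.pa - bc.pv

    def residual(q: float) -> float:
        return drive - law.dp_total(q) - bc.r_micro * q

    lo, hi = Q_BRACKET
    f_lo, f_hi = residual(lo), residual(hi)
    if not (f_lo > 0 > f_hi):
        raise HemodynamicsError(
            f"no sign change in flow bracket {Q_BRACKET} mL/s: "
            f"residual({lo})={f_lo:.3g}, residual({hi})={f_hi:.3g}; "
            f"drive={drive} mmHg, r_micro={bc.r_micro} mmHg s/mL")
    q = brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16)
    p = law.pressures(bc.pa, q)
    return HemodynamicSolution(s=g.s, q=float(q), p=p, ffr=p / bc.pa, pa=bc.pa)


def ffr_at(sol: HemodynamicSolution, pos_mm: float) -> float:
    """Linearly interpolated FFR at ``pos_mm`` (must lie inside the vessel)."""
    if pos_mm < sol.s[0] - 1e-9 or pos_mm > sol.s[-1] + 1e-9:
        raise HemodynamicsError(f"position {pos_mm} mm outside vessel "
                                f"[{sol.s[0]}, {sol.s[-1]}] mm")
    return float(np.interp(pos_mm, sol.s, sol.ffr))


def dp_between(sol: HemodynamicSolution, start_mm: float, end_mm: float) -> float:
    """Pressure drop (mmHg) between two positions read off the solution."""
    p_a = float(np.interp(start_mm, sol.s, sol.p))
    p_b = float(np.interp(end_mm, sol.s, sol.p))
    return p_a - p_b
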