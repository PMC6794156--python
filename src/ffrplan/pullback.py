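"""Simulated pressure-wire pullback and method-agreement statistics.

In a steady hyperemic model the pullback trace is simply the FFR profile read
distal-to-proximal.  The apparent FFR gradient of a lesion is the FFR step
between reading points a small margin beyond its shoulders (default 2 mm,
far enough from post-stenotic flow disturbance); its true gradient is the
same reading after every companion lesion has been virtually removed, i.e.
the lesion in isolation.  In serially diseased vessels the apparent gradient
systematically underestimates the true one, because the companion's
resistance caps hyperemic flow.

:func:`assess_cohort` computes the paired-comparison statistics used to
quantify that underestimation: mean/SD of the paired differences, mean
relative error as a proportion of the true gradient, Pearson correlation,
Bland-Altman limits of agreement (bias +/- 1.96 SD) and a TOST equivalence
test at a stated margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.weightstats import ttost_paired

from .geometry import LesionSegment, VesselGeometry, idealize
from .hemodynamics import (
    DEFAULT_FLUID,
    BoundaryCondition,
    FluidProperties,
    HemodynamicSolution,
    oracle_solve,
)

__all__ = [
    "PullbackTrace",
    "LesionAssessment",
    "AgreementReport",
    "simulate_pullback",
    "apparent_gradient",
    "ffr_true_gradient",
    "assess_cohort",
    "MARGIN_MM",
    "TOST_MARGIN",
]

MARGIN_MM = 2.0     # reading-point offset beyond lesion shoulders
TOST_MARGIN = 0.02  # default equivalence margin on FFR differences


@dataclass(frozen=True, eq=False)
class PullbackTrace:
    """FFR recorded while withdrawing the wire from distal to proximal."""

    s: np.ndarray        # positions, mm, distal first
    ffr: np.ndarray
    direction: str = "distal_to_proximal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", np.asarray(self.s, dtype=float))
        object.__setattr__(self, "ffr", np.asarray(self.ffr, dtype=float))

    def ffr_at(self, pos_mm: float) -> float:
        s_min, s_max = self.s.min(), self.s.max()
        if pos_mm < s_min - 1e-9 or pos_mm > s_max + 1e-9:
            raise ValueError(f"position {pos_mm} mm outside trace")
        order = np.argsort(self.s)
        return float(np.interp(pos_mm, self.s[order], self.ffr[order]))


@dataclass(frozen=True)
class LesionAssessment:
    """Apparent vs true FFR gradient of one lesion."""

    lesion: LesionSegment
    ffr_pullback_grad: float
    ffr_true_grad: float

    @property
    def discrepancy(self) -> float:
        return self.ffr_true_grad - self.ffr_pullback_grad

    @property
    def relative_error(self) -> float:
        """Percent error as a proportion of the true gradient."""
        if self.ffr_true_grad <= 0:
            return float("nan")
        return 100.0 * abs(self.discrepancy) / self.ffr_true_grad


def simulate_pullback(sol: HemodynamicSolution) -> PullbackTrace:
    """Pullback trace of a steady solution: the FFR profile, distal first."""
    return PullbackTrace(s=sol.s[::-1].copy(), ffr=sol.ffr[::-1].copy())


def apparent_gradient(trace: PullbackTrace,
                      lesion: LesionSegment,
                      margin: float = MARGIN_MM,
                      lesions: Sequence[LesionSegment] | None = None) -> float:
    """FFR step across a lesion read ``margin`` mm beyond its shoulders.

    Reading points are clipped to the trace; if a neighbouring lesion sits
    closer than twice the margin, the margin on that side is shrunk to half
    the gap (with a warning) so reading points never enter a companion lesion.
    Never negative.
    """
    m_prox = m_dist = margin
    if lesions:
        for other in lesions:
            if other.extent == lesion.extent:
                continue
            if other.end_mm <= lesion.start_mm + 1e-9:
                gap = lesion.start_mm - other.end_mm
                if gap < 2.0 * margin:
                    m_prox = min(m_prox, gap / 2.0)
                    warnings.warn("margin overlaps adjacent lesion; shrunk to "
                                  f"{m_prox:.2f} mm", stacklevel=2)
            elif other.start_mm >= lesion.end_mm - 1e-9:
                gap = other.start_mm - lesion.end_mm
                if gap < 2.0 * margin:
                    m_dist = min(m_dist, gap / 2.0)
                    warnings.warn("margin overlaps adjacent lesion; shrunk to "
                                  f"{m_dist:.2f} mm", stacklevel=2)
    s_min, s_max = float(trace.s.min()), float(trace.s.max())
    prox = max(lesion.start_mm - m_prox, s_min)
    dist = min(lesion.end_mm + m_dist, s_max)
    return max(0.0, trace.ffr_at(prox) - trace.ffr_at(dist))


def ffr_true_gradient(geom: VesselGeometry,
                      lesions: Sequence[LesionSegment],
                      target: LesionSegment,
                      bc: BoundaryCondition,
                      fluid: FluidProperties = DEFAULT_FLUID,
                      margin: float = MARGIN_MM) -> float:
    """True FFR gradient of ``target``: companions removed, vessel re-solved.

    Every other lesion is idealized (virtually stented), the fine-grid oracle
    re-solves the vessel, and the gradient of ``target`` is read off the new
    pullback with the same margin convention.
    """
    if target not in lesions:
        raise ValueError("target must be one of the given lesions")
    g = geom
    for les in lesions:
        if les.extent != target.extent:
            g = idealize(g, les.extent, lesions)
    sol = oracle_solve(g, bc, fluid)
    return apparent_gradient(simulate_pullback(sol), target, margin,
                             lesions=[target])


# ---------------------------------------------------------------------------
# agreement statistics

@dataclass(frozen=True)
class AgreementReport:
    """Paired-comparison statistics between an estimator and the truth.

    Differences are ``true - estimated``, so a positive bias means the
    estimator underestimates.  ``bland_altman`` holds the bias and the
    1.96-SD limits of agreement; ``tost_p`` is the two-one-sided-tests
    equivalence p-value at ``tost_margin``.
    """

    n: int
    mean_diff: float
    sd_diff: float
    mean_relative_error_pct: float
    pearson_r: float
    bland_altman: dict[str, float]
    paired_t_p: float
    tost_p: float
    tost_margin: float

    def to_json_dict(self) -> dict:
        return {
            "n": self.n, "mean_diff": self.mean_diff, "sd_diff": self.sd_diff,
            "mean_relative_error_pct": self.mean_relative_error_pct,
            "pearson_r": self.pearson_r, "bland_altman": dict(self.bland_altman),
            "paired_t_p": self.paired_t_p, "tost_p": self.tost_p,
            "tost_margin": self.tost_margin,
        }


def assess_cohort(pairs: Sequence[tuple[float, float]],
                  tost_margin: float = TOST_MARGIN) -> AgreementReport:
    """Agreement statistics over ``(estimated, true)`` gradient pairs.

    Requires at least two pairs and strictly positive true gradients (they
    normalise the relative error).  Degenerate inputs (zero-variance
    differences, constant estimates) yield NaN for the affected test
    statistics rather than an error.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (estimated, true) pairs")
    est, true = arr[:, 0], arr[:, 1]
    if np.any(true <= 0):
        raise ValueError("true gradients must be positive")
    diff = true - est
    n = int(arr.shape[0])
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    rel = float(np.mean(100.0 * np.abs(diff) / true))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if np.ptp(est) == 0 or np.ptp(true) == 0:
            pearson = float("nan")
        else:
            pearson = float(sps.pearsonr(est, true).statistic)
        if sd_diff == 0.0:
            t_p = float("nan") if mean_diff != 0 else 1.0
            tost_p = float("nan")
        else:
            t_p = float(sps.ttest_rel(true, est).pvalue)
            tost_p = float(ttost_paired(est, true, -tost_margin, tost_margin)[0])
    return AgreementReport(
        n=n, mean_diff=mean_diff, sd_diff=sd_diff,
        mean_relative_error_pct=rel, pearson_r=pearson,
        bland_altman={"bias": mean_diff,
                      "lo": mean_diff - 1.96 * sd_diff,
                      "hi": mean_diff + 1.96 * sd_diff},
        paired_t_p=t_p, tost_p=tost_p, tost_margin=tost_margin,
    )
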