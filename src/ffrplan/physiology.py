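"""Hyperemic microvascular boundary conditions from physiological principles.

Resting coronary flow is tied to the subtended myocardial mass through an
allometric scaling law, ``Q_rest = q_scale * mass^k`` (metabolic exponent
``k = 0.75`` by default), and maximal hyperemia is modelled as a predictable
multiplicative reduction of the resting microvascular resistance
(``hyperemia_factor = 0.24`` by default, the canonical adenosine response
used throughout the CT-FFR literature).  Both are configurable because the
population-derived models behind clinical CT-FFR products are proprietary;
only the stated principles are implemented here, and the lumen-volume term of
the scaling law is omitted for this single-conduit tool.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hemodynamics import BoundaryCondition

__all__ = ["PhysiologyModel", "resting_flow", "hyperemic_bc"]


@dataclass(frozen=True)
class PhysiologyModel:
    """Allometric resting-flow and hyperemia parameters.

    Parameters
    ----------
    myocardial_mass : float
        Subtended myocardial mass, g.
    q_scale : float
        Flow coefficient of the scaling law, mL/s per g^k.
    k : float
        Allometric exponent, dimensionless, in (0, 1].
    hyperemia_factor : float
        Multiplicative microvascular-resistance reduction under maximal
        hyperemia, in (0, 1).
    """

    myocardial_mass: float = 90.0
    q_scale: float = 0.015
    k: float = 0.75
    hyperemia_factor: float = 0.24

    def __post_init__(self) -> None:
        if self.myocardial_mass <= 0:
            raise ValueError("myocardial mass must be positive")
        if self.q_scale <= 0:
            raise ValueError("q_scale must be positive")
        if not 0.0 < self.k <= 1.0:
            raise ValueError("k must lie in (0, 1]")
        if not 0.0 < self.hyperemia_factor < 1.0:
            raise ValueError("hyperemia_factor must lie in (0, 1)")


def resting_flow(model: PhysiologyModel) -> float:
    """Resting coronary flow ``q_scale * mass^k`` in mL/s."""
    return model.q_scale * model.myocardial_mass ** model.k


def hyperemic_bc(model: PhysiologyModel, pa: float, pv: float = 0.0) -> BoundaryCondition:
    """Hyperemic boundary condition for a vessel perfused at ``pa``/``pv``.

    The resting microvascular resistance absorbs the full driving pressure at
    resting flow, ``R_rest = (pa - pv) / Q_rest``; hyperemia scales it down by
    ``hyperemia_factor``.  Through a disease-free vessel the hyperemic flow is
    therefore ``Q_rest / hyperemia_factor`` up to epicardial viscous losses.
    """
    if not pa > pv:
        raise ValueError("require pa > pv")
    r_rest = (pa - pv) / resting_flow(model)
    return BoundaryCondition(pa=pa, pv=pv, r_micro=model.hyperemia_factor * r_rest)
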