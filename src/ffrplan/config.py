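"""Run configuration: defaults, YAML loading and validation.

Every tunable of the tool chain lives here with its unit in the key name.
``RunConfig.default()`` carries the study conditions; a YAML file only needs
the keys it overrides.  ``ffrplan config --dump`` prints the full default
document.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .cohort import CohortSpec
from .hemodynamics import ORACLE_DS_MM, FluidProperties
from .physiology import PhysiologyModel
from .pullback import MARGIN_MM, TOST_MARGIN
from .reduced_order import FLOW_TOL_ML_S

__all__ = ["RunConfig", "load_config", "dump_default_config"]

STENT_POLICIES = ("most_severe", "proximal", "distal")


@dataclass(frozen=True)
class RunConfig:
    fluid: FluidProperties = field(default_factory=FluidProperties)
    physiology: PhysiologyModel = field(default_factory=PhysiologyModel)
    pa_mmHg: float = 90.0
    pv_mmHg: float = 0.0
    oracle_ds_mm: float = ORACLE_DS_MM
    flow_tol_ml_s: float = FLOW_TOL_ML_S
    margin_mm: float = MARGIN_MM
    tost_margin: float = TOST_MARGIN
    detect_min_pct: float = 30.0
    detect_min_gap_mm: float = 10.0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    stent_policy: str = "most_severe"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stent_policy not in STENT_POLICIES:
            raise ValueError(f"stent_policy must be one of {STENT_POLICIES}")
        if not self.pa_mmHg > self.pv_mmHg >= 0:
            raise ValueError("require pa_mmHg > pv_mmHg >= 0")

    def to_dict(self) -> dict:
        return {
            "fluid": {"mu_pa_s": self.fluid.mu, "rho_kg_m3": self.fluid.rho},
            "physiology": {
                "myocardial_mass_g": self.physiology.myocardial_mass,
                "q_scale": self.physiology.q_scale,
                "k": self.physiology.k,
                "hyperemia_factor": self.physiology.hyperemia_factor,
            },
            "boundary": {"pa_mmHg": self.pa_mmHg, "pv_mmHg": self.pv_mmHg},
            "solver": {
                "oracle_ds_mm": self.oracle_ds_mm,
                "flow_tol_ml_s": self.flow_tol_ml_s,
                "margin_mm": self.margin_mm,
                "tost_margin": self.tost_margin,
            },
            "lesion_detection": {
                "min_pct": self.detect_min_pct,
                "min_gap_mm": self.detect_min_gap_mm,
            },
            "cohort": {
                "n_vessels": self.cohort.n_vessels,
                "seed": self.cohort.seed,
                "length_range_mm": list(self.cohort.length_range),
                "inlet_radius_range_mm": list(self.cohort.inlet_radius_range),
                "taper_pct_range": list(self.cohort.taper_pct_range),
                "n_lesions": self.cohort.n_lesions,
                "ds_range_pct": list(self.cohort.ds_range),
                "lesion_len_range_mm": list(self.cohort.lesion_len_range),
                "min_gap_mm": self.cohort.min_gap,
                "sample_ds_mm": self.cohort.sample_ds,
            },
            "stent_policy": self.stent_policy,
            "seed": self.seed,
        }

    @staticmethod
    def default() -> "RunConfig":
        return RunConfig()


def _merge(cfg: RunConfig, doc: dict) -> RunConfig:
    fluid = cfg.fluid
    if "fluid" in doc:
        d = doc["fluid"]
        fluid = FluidProperties(mu=d.get("mu_pa_s", fluid.mu),
                                rho=d.get("rho_kg_m3", fluid.rho))
    phys = cfg.physiology
    if "physiology" in doc:
        d = doc["physiology"]
        phys = PhysiologyModel(
            myocardial_mass=d.get("myocardial_mass_g", phys.myocardial_mass),
            q_scale=d.get("q_scale", phys.q_scale),
            k=d.get("k", phys.k),
            hyperemia_factor=d.get("hyperemia_factor", phys.hyperemia_factor))
    bnd = doc.get("boundary", {})
    sol = doc.get("solver", {})
    det = doc.get("lesion_detection", {})
    coh = cfg.cohort
    if "cohort" in doc:
        d = doc["cohort"]
        coh = CohortSpec(
            n_vessels=d.get("n_vessels", coh.n_vessels),
            seed=d.get("seed", coh.seed),
            length_range=tuple(d.get("length_range_mm", coh.length_range)),
            inlet_radius_range=tuple(
                d.get("inlet_radius_range_mm", coh.inlet_radius_range)),
            taper_pct_range=tuple(d.get("taper_pct_range", coh.taper_pct_range)),
            n_lesions=d.get("n_lesions", coh.n_lesions),
            ds_range=tuple(d.get("ds_range_pct", coh.ds_range)),
            lesion_len_range=tuple(
                d.get("lesion_len_range_mm", coh.lesion_len_range)),
            min_gap=d.get("min_gap_mm", coh.min_gap),
            sample_ds=d.get("sample_ds_mm", coh.sample_ds))
    return RunConfig(
        fluid=fluid, physiology=phys,
        pa_mmHg=bnd.get("pa_mmHg", cfg.pa_mmHg),
        pv_mmHg=bnd.get("pv_mmHg", cfg.pv_mmHg),
        oracle_ds_mm=sol.get("oracle_ds_mm", cfg.oracle_ds_mm),
        flow_tol_ml_s=sol.get("flow_tol_ml_s", cfg.flow_tol_ml_s),
        margin_mm=sol.get("margin_mm", cfg.margin_mm),
        tost_margin=sol.get("tost_margin", cfg.tost_margin),
        detect_min_pct=det.get("min_pct", cfg.detect_min_pct),
        detect_min_gap_mm=det.get("min_gap_mm", cfg.detect_min_gap_mm),
        cohort=coh,
        stent_policy=doc.get("stent_policy", cfg.stent_policy),
        seed=doc.get("seed", cfg.seed))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Defaults, overridden by the keys present in the YAML file (if any)."""
    cfg = RunConfig.default()
    if path is None:
        return cfg
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return _merge(cfg, doc)


def dump_default_config() -> str:
    return yaml.safe_dump(RunConfig.default().to_dict(), sort_keys=False)
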