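"""Seeded generator of synthetic serially stenosed vessels.

Each vessel is a linearly tapering conduit carrying raised-cosine narrowings
(smooth dips that return exactly to the healthy taper at their shoulders).
The defaults emulate the anatomy a serial-disease PCI study enrols: vessels
80-140 mm long with two stenoses of 40-85% diameter stenosis and 8-25 mm
length, separated by at least 10 mm of normal lumen and kept clear of the
vessel ends.  Under the default hyperemic physiology this cohort's
total-vessel FFR spans roughly 0.4-0.95 with a mean near 0.67.

Randomness comes from one named ``numpy`` generator seeded per vessel with
``(seed, index)``, so cohorts are reproducible and order-independent; the
same pair always regenerates the vessel bit-identically.

What this generator does *not* emulate: CT segmentation noise, eccentric or
non-axisymmetric lesions, bifurcations and branch flow loss, and aneurysmal
ectasia.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .geometry import LesionSegment, VesselGeometry

__all__ = ["CohortSpec", "generate_vessel", "generate_cohort", "cohort_manifest"]

_MAX_TRIES = 1000


@dataclass(frozen=True)
class CohortSpec:
    """Sampling law of the synthetic cohort (lengths mm, severities %DS)."""

    n_vessels: int = 100
    seed: int = 0
    length_range: tuple[float, float] = (80.0, 140.0)
    inlet_radius_range: tuple[float, float] = (1.4, 2.2)
    taper_pct_range: tuple[float, float] = (10.0, 30.0)
    n_lesions: int = 2
    ds_range: tuple[float, float] = (40.0, 85.0)
    lesion_len_range: tuple[float, float] = (8.0, 25.0)
    min_gap: float = 10.0
    sample_ds: float = 0.25
    edge_margin: float = 5.0

    def __post_init__(self) -> None:
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be >= 1")
        if self.min_gap < 10.0:
            raise ValueError("serial lesions must be separated by >= 10 mm "
                             "of normal lumen")
        lo, hi = self.ds_range
        if not (30.0 < lo <= hi < 95.0):
            raise ValueError("ds_range must lie within (30, 95) %DS")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if self.sample_ds <= 0 or self.sample_ds > 1.0:
            raise ValueError("sample_ds must be in (0, 1] mm")


def _vessel_rng(spec: CohortSpec, index: int) -> np.random.Generator:
    """Per-vessel substream: PCG64 seeded with the (seed, index) pair."""
    return np.random.default_rng([spec.seed, index])


def generate_vessel(spec: CohortSpec, index: int
                    ) -> tuple[VesselGeometry, list[LesionSegment]]:
    """One synthetic vessel plus its ground-truth lesion records.

    The baseline radius tapers linearly from the sampled inlet radius; each
    lesion multiplies it by ``1 - d * w(s)`` where ``w`` is a raised cosine
    over the lesion extent (``w = 0`` at the shoulders, ``1`` at the centre)
    and ``d = pct_ds / 100``.  Placement is by rejection sampling until the
    gap and end-margin constraints hold.
    """
    rng = _vessel_rng(spec, index)
    length = rng.uniform(*spec.length_range)
    r_in = rng.uniform(*spec.inlet_radius_range)
    taper = rng.uniform(*spec.taper_pct_range) / 100.0
    n = int(np.ceil(length / spec.sample_ds)) + 1
    s = np.linspace(0.0, length, n)
    r_base = r_in * (1.0 - taper * s / length)

    for _ in range(_MAX_TRIES):
        lens = rng.uniform(*spec.lesion_len_range, size=spec.n_lesions)
        depths = rng.uniform(*spec.ds_range, size=spec.n_lesions) / 100.0
        span = length - 2.0 * spec.edge_margin
        if lens.sum() + (spec.n_lesions - 1) * spec.min_gap > span:
            continue
        starts = np.sort(rng.uniform(spec.edge_margin,
                                     length - spec.edge_margin,
                                     size=spec.n_lesions))
        ok = True
        prev_end = None
        for st, ln in zip(starts, lens):
            if st + ln > length - spec.edge_margin:
                ok = False
                break
            if prev_end is not None and st - prev_end < spec.min_gap:
                ok = False
                break
            prev_end = st + ln
        if ok:
            break
    else:
        raise RuntimeError(
            f"could not place {spec.n_lesions} lesions of "
            f"{spec.lesion_len_range} mm with {spec.min_gap} mm gaps in a "
            f"{length:.0f} mm vessel after {_MAX_TRIES} tries")

    r = r_base.copy()
    records = []
    for st, ln, d in zip(starts, lens, depths):
        end = st + ln
        inside = (s >= st) & (s < end)
        w = 0.5 * (1.0 - np.cos(2.0 * np.pi * (s[inside] - st) / ln))
        r[inside] = r[inside] * (1.0 - d * w)
        records.append((float(st), float(end)))

    geom = VesselGeometry(s, r, label=f"synthetic:{spec.seed}:{index}")
    lesions = []
    for st, end in records:
        mask = (s >= st) & (s < end)
        idx = np.flatnonzero(mask)
        k = int(idx[np.argmin(r[mask])])
        # reference at the throat: flank-to-flank interpolation, which for a
        # linear taper is exactly the undiseased baseline
        j0 = max(int(idx[0]) - 1, 0)
        j1 = min(int(idx[-1]) + 1, n - 1)
        r_ref = float(r[j0] + (r[j1] - r[j0]) * (s[k] - s[j0]) / (s[j1] - s[j0]))
        r_min = float(r[k])
        lesions.append(LesionSegment(st, end, r_min, r_ref,
                                     100.0 * (1.0 - r_min / r_ref)))
    return geom, lesions


def generate_cohort(spec: CohortSpec
                    ) -> list[tuple[VesselGeometry, list[LesionSegment]]]:
    """All ``spec.n_vessels`` vessels, from independent per-index substreams."""
    return [generate_vessel(spec, i) for i in range(spec.n_vessels)]


def cohort_manifest(cohort: Sequence[tuple[VesselGeometry, list[LesionSegment]]]
                    ) -> pd.DataFrame:
    """Ground-truth table: one row per lesion with vessel id and geometry."""
    rows = []
    for i, (geom, lesions) in enumerate(cohort):
        for j, les in enumerate(lesions):
            rows.append({
                "vessel_id": i, "label": geom.label,
                "length_mm": geom.length, "lesion_idx": j,
                "start_mm": les.start_mm, "end_mm": les.end_mm,
                "r_min_mm": les.r_min, "r_ref_mm": les.r_ref,
                "pct_ds": les.pct_ds,
            })
    return pd.DataFrame(rows)
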