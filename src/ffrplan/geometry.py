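"""Vessel lumen geometry: radius profiles, lesion detection and idealization.

A vessel is represented as a sampled lumen-radius profile ``r(s)`` along the
centerline arc length ``s`` measured from the ostium.  All geometric
quantities are in millimetres; intervals along the vessel are half-open
``[start, end)``.

The healthy ("reference") lumen at a diseased location is estimated the way
quantitative coronary angiography does it: by linear interpolation between the
nearest angiographically normal flank samples.  Percent diameter stenosis is
``100 * (1 - r_min / r_ref)``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GeometryError",
    "VesselGeometry",
    "LesionSegment",
    "StentPlan",
    "resample",
    "reference_profile",
    "percent_stenosis",
    "detect_lesions",
    "idealize",
    "segment_vessel",
    "read_vessel_csv",
    "write_vessel_csv",
    "lesions_to_json",
    "lesions_from_json",
]

#: minimal narrowing (percent of reference diameter) treated as "diseased"
#: when tracing the full extent of a lesion back to its healthy shoulders.
EDGE_PCT = 0.02

MIN_SAMPLES = 10


class GeometryError(ValueError):
    """Invalid vessel geometry or lesion description."""


@dataclass(frozen=True, eq=False)
class VesselGeometry:
    """Sampled lumen radius versus arc length.

    Parameters
    ----------
    s : array-like
        Arc length from the ostium, mm, strictly increasing, >= 10 samples.
    r : array-like
        Lumen radius at each sample, mm, all positive.
    label : str
        Free-text identifier carried through I/O.
    """

    s: np.ndarray
    r: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if s.ndim != 1 or r.ndim != 1 or s.size != r.size:
            raise GeometryError("s and r must be 1-D arrays of equal length")
        if s.size < MIN_SAMPLES:
            raise GeometryError(f"need at least {MIN_SAMPLES} samples, got {s.size}")
        if not np.all(np.diff(s) > 0):
            raise GeometryError("arc-length samples must be strictly increasing")
        if not np.all(r > 0):
            raise GeometryError("all lumen radii must be positive")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "r", r)

    @property
    def length(self) -> float:
        """Vessel length covered by the profile, mm."""
        return float(self.s[-1] - self.s[0])

    def radius_at(self, pos_mm: float | np.ndarray) -> float | np.ndarray:
        """Linearly interpolated lumen radius at ``pos_mm`` (must lie inside)."""
        pos = np.asarray(pos_mm, dtype=float)
        if np.any(pos < self.s[0] - 1e-9) or np.any(pos > self.s[-1] + 1e-9):
            raise GeometryError(f"position {pos_mm} outside vessel "
                                f"[{self.s[0]}, {self.s[-1]}] mm")
        out = np.interp(pos, self.s, self.r)
        return float(out) if np.isscalar(pos_mm) else out

    def sample_mask(self, start_mm: float, end_mm: float) -> np.ndarray:
        """Boolean mask of samples in the half-open interval [start, end)."""
        return (self.s >= start_mm - 1e-9) & (self.s < end_mm - 1e-9)


@dataclass(frozen=True)
class LesionSegment:
    """A contiguous diseased extent ``[start_mm, end_mm)``.

    ``r_min`` is the minimal lumen radius inside the extent, ``r_ref`` the
    estimated healthy radius at that same location and ``pct_ds`` the percent
    diameter stenosis ``100 * (1 - r_min / r_ref)``.
    """

    start_mm: float
    end_mm: float
    r_min: float
    r_ref: float
    pct_ds: float

    def __post_init__(self) -> None:
        if not self.end_mm > self.start_mm:
            raise GeometryError("lesion extent must have end_mm > start_mm")
        if not (0.0 <= self.pct_ds < 100.0):
            raise GeometryError("pct_ds must lie in [0, 100)")
        expected = 100.0 * (1.0 - self.r_min / self.r_ref)
        if abs(self.pct_ds - expected) > 0.5:
            raise GeometryError(
                f"pct_ds={self.pct_ds:.3f} inconsistent with "
                f"r_min/r_ref ({expected:.3f})")

    @property
    def extent(self) -> tuple[float, float]:
        return (self.start_mm, self.end_mm)

    @property
    def length(self) -> float:
        return self.end_mm - self.start_mm


@dataclass(frozen=True)
class StentPlan:
    """A stented extent ``[start_mm, end_mm)`` along the vessel."""

    start_mm: float
    end_mm: float

    def __post_init__(self) -> None:
        if not self.end_mm > self.start_mm:
            raise GeometryError("stent extent must have end_mm > start_mm")

    @property
    def length(self) -> float:
        return self.end_mm - self.start_mm


# ---------------------------------------------------------------------------
# resampling

def resample(geom: VesselGeometry, ds: float) -> VesselGeometry:
    """Resample the profile on a uniform grid of spacing <= ``ds``.

    The endpoints are preserved; the actual spacing is the largest uniform
    spacing not exceeding ``ds`` that divides the length evenly.  Radii are
    linearly interpolated, so resampling twice at the same ``ds`` is a no-op.
    """
    if ds <= 0:
        raise GeometryError("ds must be positive")
    n = int(np.ceil(geom.length / ds - 1e-12)) + 1
    s_new = np.linspace(geom.s[0], geom.s[-1], n)
    r_new = np.interp(s_new, geom.s, geom.r)
    return VesselGeometry(s_new, r_new, geom.label)


# ---------------------------------------------------------------------------
# reference (healthy) lumen

def _check_extent(geom: VesselGeometry, start: float, end: float) -> None:
    if not end > start:
        raise GeometryError("extent must have end > start")
    if start < geom.s[0] - 1e-9 or end > geom.s[-1] + 1e-9:
        raise GeometryError(
            f"extent [{start}, {end}) outside vessel "
            f"[{geom.s[0]}, {geom.s[-1]}] mm")


def reference_profile(geom: VesselGeometry,
                      lesions: Sequence[LesionSegment]) -> VesselGeometry:
    """Healthy-radius estimate at every sample.

    Outside the given lesion extents the vessel is taken to be normal, so the
    reference equals the measured radius.  Inside each lesion the reference is
    the straight line between the nearest flank samples, mirroring the
    interpolated reference diameter of quantitative coronary angiography.
    """
    s, r = geom.s, geom.r
    ref = r.copy()
    for les in sorted(lesions, key=lambda l: l.start_mm):
        _check_extent(geom, les.start_mm, les.end_mm)
        inside = geom.sample_mask(les.start_mm, les.end_mm)
        if not inside.any():
            continue
        i0 = int(np.argmax(inside))
        i1 = int(len(s) - 1 - np.argmax(inside[::-1]))
        if i0 == 0 or i1 == len(s) - 1:
            raise GeometryError(
                "lesion touches a vessel endpoint; no healthy flank to anchor "
                "the reference radius")
        j0, j1 = i0 - 1, i1 + 1
        ref[inside] = r[j0] + (r[j1] - r[j0]) * (s[inside] - s[j0]) / (s[j1] - s[j0])
    clamped = ref < r - 1e-12
    if clamped.any():
        log.warning("aneurysmal samples (r > reference) clamped to measured "
                    "radius at %d sample(s)", int(clamped.sum()))
        ref = np.maximum(ref, r)
    return VesselGeometry(s, ref, geom.label + ":reference" if geom.label else "reference")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as inclusive (start_idx, end_idx) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[brk + 1]]
    ends = np.r_[idx[brk], idx[-1]]
    return list(zip(starts.tolist(), ends.tolist()))


def _baseline_fit(geom: VesselGeometry) -> np.ndarray:
    """Robust straight-line (tapered tube) fit to the healthy lumen.

    Stenoses only narrow the lumen, so healthy samples form the upper envelope
    of the profile: iteratively refit a line keeping samples at or above it,
    with a shrinking tolerance.  Exact for noiseless linearly tapered vessels;
    for noisy clinical profiles the shrinking tolerance makes the fit lean on
    the most collinear healthy samples.
    """
    s, r = geom.s, geom.r
    mask = np.ones(s.size, dtype=bool)
    tol = 0.10
    for _ in range(14):
        coef = np.polyfit(s[mask], r[mask], 1)
        fit = np.polyval(coef, s)
        cand = r >= fit * (1.0 - tol)
        if cand.sum() >= MIN_SAMPLES:
            mask = cand
        tol = max(tol * 0.5, 1e-9)
    return np.polyval(np.polyfit(s[mask], r[mask], 1), s)


def auto_reference(geom: VesselGeometry, edge_pct: float = EDGE_PCT) -> np.ndarray:
    """Healthy-radius estimate without a prior lesion list.

    Fits a robust tapered baseline, marks samples narrowed by more than
    ``edge_pct`` percent as diseased, and replaces each diseased run by the
    flank-to-flank interpolation used by :func:`reference_profile`.  Runs
    touching a vessel endpoint fall back to the fitted baseline.
    """
    s, r = geom.s, geom.r
    base = _baseline_fit(geom)
    narrow = 100.0 * (1.0 - r / base)
    ref = r.copy()
    for i0, i1 in _runs(narrow > edge_pct):
        if i0 == 0 or i1 == s.size - 1:
            ref[i0:i1 + 1] = np.maximum(base[i0:i1 + 1], r[i0:i1 + 1])
            continue
        j0, j1 = i0 - 1, i1 + 1
        sl = slice(i0, i1 + 1)
        ref[sl] = r[j0] + (r[j1] - r[j0]) * (s[sl] - s[j0]) / (s[j1] - s[j0])
    return np.maximum(ref, r)


def percent_stenosis(geom: VesselGeometry,
                     extent: tuple[float, float],
                     lesions: Sequence[LesionSegment] | None = None) -> float:
    """Percent diameter stenosis of the worst sample inside ``extent``.

    ``100 * (1 - r_min / r_ref)`` with ``r_min`` the minimum sampled radius in
    the extent and ``r_ref`` the reference radius at that sample.  If a lesion
    list is given the reference comes from :func:`reference_profile`;
    otherwise it is estimated with :func:`auto_reference`.
    """
    start, end = extent
    _check_extent(geom, start, end)
    mask = geom.sample_mask(start, end)
    if not mask.any():
        raise GeometryError("extent contains no samples")
    if lesions is None:
        ref = auto_reference(geom)
    else:
        ref = reference_profile(geom, lesions).r
    k = int(np.flatnonzero(mask)[np.argmin(geom.r[mask])])
    return max(0.0, 100.0 * (1.0 - geom.r[k] / ref[k]))


def detect_lesions(geom: VesselGeometry,
                   min_pct: float = 30.0,
                   min_gap: float = 10.0,
                   edge_pct: float = EDGE_PCT) -> list[LesionSegment]:
    """Find maximal diseased extents narrowed by more than ``min_pct``.

    Each core region exceeding ``min_pct`` percent diameter stenosis is
    expanded outward to its healthy shoulders (narrowing <= ``edge_pct``),
    then extents separated by less than ``min_gap`` mm of normal lumen are
    merged.  Returns one :class:`LesionSegment` per extent (possibly empty).
    """
    if not 0.0 < min_pct < 100.0:
        raise GeometryError("min_pct must be in (0, 100)")
    s, r = geom.s, geom.r
    ref = auto_reference(geom, edge_pct)
    narrow = 100.0 * (1.0 - r / ref)
    extents: list[list[float]] = []
    for c0, c1 in _runs(narrow > min_pct):
        i0, i1 = c0, c1
        while i0 > 0 and narrow[i0 - 1] > edge_pct:
            i0 -= 1
        while i1 < s.size - 1 and narrow[i1 + 1] > edge_pct:
            i1 += 1
        # include one healthy guard sample proximally; the half-open end sits
        # at the first healthy sample distally, keeping both boundaries within
        # one sample spacing of the true shoulders.
        start = s[max(i0 - 1, 0)]
        end = s[min(i1 + 1, s.size - 1)]
        extents.append([float(start), float(end)])
    merged: list[list[float]] = []
    for ext in extents:
        if merged and ext[0] - merged[-1][1] < min_gap:
            merged[-1][1] = max(merged[-1][1], ext[1])
        else:
            merged.append(ext)
    lesions = []
    for start, end in merged:
        mask = geom.sample_mask(start, end)
        k = int(np.flatnonzero(mask)[np.argmin(r[mask])])
        r_min = float(r[k])
        r_ref = float(ref[k])
        lesions.append(LesionSegment(start, end, r_min, r_ref,
                                     max(0.0, 100.0 * (1.0 - r_min / r_ref))))
    return lesions


def idealize(geom: VesselGeometry,
             extent: tuple[float, float],
             lesions: Sequence[LesionSegment]) -> VesselGeometry:
    """Replace radii inside ``extent`` by their disease-free reference values.

    Samples outside the extent are untouched.  Re-applying the same extent is
    a no-op, and percent stenosis of any sub-extent of ``extent`` is zero
    within tolerance afterwards.
    """
    start, end = extent
    _check_extent(geom, start, end)
    ref = reference_profile(geom, lesions)
    mask = geom.sample_mask(start, end)
    r_new = geom.r.copy()
    r_new[mask] = ref.r[mask]
    return VesselGeometry(geom.s, r_new, geom.label)


def segment_vessel(geom: VesselGeometry,
                   lesions: Sequence[LesionSegment]) -> list[tuple[float, float]]:
    """Tile the vessel into alternating healthy / lesion extents.

    Returns the ordered list of half-open intervals covering ``[s0, s_end)``:
    one per lesion plus one per inter-lesion (and end-cap) healthy stretch.
    Zero-length pieces are dropped; lesions must not overlap.
    """
    bounds = [float(geom.s[0])]
    for les in sorted(lesions, key=lambda l: l.start_mm):
        _check_extent(geom, les.start_mm, les.end_mm)
        if les.start_mm < bounds[-1] - 1e-9:
            raise GeometryError("lesion extents overlap")
        bounds.extend([les.start_mm, les.end_mm])
    bounds.append(float(geom.s[-1]))
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a > 1e-9:
            out.append((float(a), float(b)))
    return out


# ---------------------------------------------------------------------------
# I/O

def write_vessel_csv(geom: VesselGeometry, path: str | Path) -> None:
    """Write the profile as ``s_mm,r_mm`` CSV with an optional label comment."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if geom.label:
            fh.write(f"# label={geom.label}\n")
        fh.write("s_mm,r_mm\n")
        for s, r in zip(geom.s, geom.r):
            fh.write(f"{float(s)!r},{float(r)!r}\n")


def read_vessel_csv(path: str | Path) -> VesselGeometry:
    """Read a ``s_mm,r_mm`` profile written by :func:`write_vessel_csv`."""
    path = Path(path)
    label = ""
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("#"):
            if "label=" in stripped:
                label = stripped.split("label=", 1)[1].strip()
            continue
        if stripped:
            body.append(stripped)
    if not body or body[0].replace(" ", "") != "s_mm,r_mm":
        raise GeometryError(f"{path}: expected header 's_mm,r_mm'")
    try:
        data = np.array([[float(x) for x in row.split(",")] for row in body[1:]])
    except ValueError as exc:
        raise GeometryError(f"{path}: malformed numeric row ({exc})") from exc
    if data.ndim != 2 or data.shape[1] != 2:
        raise GeometryError(f"{path}: each row must have exactly two columns")
    return VesselGeometry(data[:, 0], data[:, 1], label)


def lesions_to_json(lesions: Sequence[LesionSegment]) -> str:
    return json.dumps([
        {"start_mm": l.start_mm, "end_mm": l.end_mm, "r_min_mm": l.r_min,
         "r_ref_mm": l.r_ref, "pct_ds": l.pct_ds}
        for l in lesions
    ], indent=2)


def lesions_from_json(text: str) -> list[LesionSegment]:
    raw = json.loads(text)
    return [LesionSegment(d["start_mm"], d["end_mm"], d["r_min_mm"],
                          d["r_ref_mm"], d["pct_ds"]) for d in raw]
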