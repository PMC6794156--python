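# Methods

## Model overview

`ffrplan` treats a coronary artery as a single rigid conduit described by its
lumen radius `r(s)` sampled along the centerline arc length `s` (mm from the
ostium). Flow is steady, Newtonian and incompressible; FFR is the steady
hyperemic pressure ratio `p(s)/Pa`. A cycle-averaged invasive FFR has no
pulsatile content that a steady 0D/1D model must reproduce, so no
wave-propagation machinery is used.

Two solvers share one constitutive law:

1. a **fine-grid solver** (`hemodynamics.oracle_solve`) that evaluates the
   law sample-by-sample on a 0.05 mm grid — the package's ground truth and
   the stand-in for full 3D CFD;
2. a **reduced-order network** (`reduced_order`) of per-segment
   flow-dependent resistances `R(Q) = R_in + R_sl·Q`, calibrated against the
   fine-grid solver and re-solvable in closed form — the engine behind the
   interactive PCI planner.

## Pressure-drop law

Over any extent the epicardial drop is

    ΔP(Q) = R_v·Q + S·Q|Q|

* `R_v = ∫ 8πμ/A(s)² ds` — the Poiseuille integral of the sampled lumen
  (`A = πr²`), evaluated by the trapezoid rule with interpolated extent
  endpoints.
* `S = (Kt·ρ/2)(1/A_min − 1/A_out)²` — the irreversible expansion
  (flow-separation) loss of a narrowing with throat area `A_min` recovering
  to the downstream healthy area `A_out`; `Kt = 1.52`, the classical
  empirical expansion coefficient.

Internally everything is SI; the interface uses mmHg, mL/s and mm with the
fixed conversion 1 mmHg = 133.322 Pa.

The fine-grid solver finds expansion-loss sites automatically: every maximal
run of the profile narrowed by more than 0.5% against the healthy reference
contributes one `S` term, with the run expanded to its healthy shoulders so
`A_out` is the fully recovered lumen. The irreversible drop is ramped
linearly from the throat to the distal shoulder, which keeps the pressure
profile non-increasing and localises each FFR step at its lesion. Site
detection is internal to the solver — ground truth does not depend on how the
caller labels lesions clinically.

The operating point solves `Pa − Pv = ΔP_epicardial(Q) + R_micro·Q` by Brent
root-finding on the bracket [1e−6, 50] mL/s (xtol 1e−12); no sign change in
the bracket is a hard error with a diagnostic.

## Healthy reference lumen and lesion grading

The "no lumen narrowing" radius at a diseased sample is the straight line
between the nearest healthy flank samples — the interpolated reference
diameter convention of quantitative coronary angiography. Percent diameter
stenosis is `100·(1 − r_min/r_ref)`.

When no lesion list is supplied, the healthy baseline is found by a robust
tapered-tube fit: stenoses only narrow the lumen, so healthy samples form the
upper envelope; a straight line is refit iteratively keeping samples at or
above it with a shrinking tolerance. This is exact for noiseless linearly
tapering vessels (which the generator emits) and is the stated limitation
for strongly non-linear or noisy baselines. Detected lesion extents are the
threshold-crossing cores expanded out to shoulders narrowed by ≤ 0.02%, with
one guard sample proximally, so planted extents are recovered within one
sample spacing; extents separated by less than `min_gap` are merged.
Aneurysmal samples (r above reference) are clamped to the measured radius
and logged — ectasia is not modelled.

## Hyperemic boundary condition

Resting flow follows the allometric law `Q_rest = q_scale·mass^k` with
`k = 0.75` (metabolic allometry) and `mass = 90 g` of subtended myocardium.
The resting microvascular resistance absorbs the full driving pressure at
`Q_rest`; maximal hyperemia multiplies it by `hyperemia_factor = 0.24`, the
canonical adenosine response. `q_scale = 0.015 mL/s/g^0.75` places the
default synthetic cohort's total-vessel hyperemic FFR at about 0.66 ± 0.22 —
the severity of a representative serial-disease PCI population — at the cost
of a resting flow (≈ 0.44 mL/s) at the low end of the physiological range.
All four parameters are configurable; the lumen-volume term used by clinical
CT-FFR products is omitted because a single conduit has no tree to
distribute flow over.

## Calibration of the reduced-order model

The vessel is tiled into one segment per lesion plus one per healthy stretch
(granularity chosen so serial-lesion interplay stays representable). Two
whole-vessel fine-grid solutions are computed: hyperemia, and hyperemia with
the microvascular resistance lowered by 40% (`R_micro ← 0.6·R_micro`). With
flows `Q < Q*` and per-segment resistances `R = ΔP/Q`, `R* = ΔP*/Q*`:

    R_sl = (R* − R)/(Q* − Q),    R_in = R − R_sl·Q

The two-point fit is exact at both calibration points by construction.
`Q* ≤ Q` indicates solver failure and is an error. If `Q* − Q <
flow_tol = 0.05 mL/s` (severe disease pinning the flow), the segment falls
back to the analytic coefficients `R_in = R_v`, `R_sl = S` of its extent.

Because the 1D ground truth is itself linear-plus-quadratic in flow, the
calibrated network reproduces the fine-grid solution to near machine
precision on the same geometry; the cohort-scale equivalence checks
(mean |ΔFFR| ≤ 0.01, max ≤ 0.03, TOST at ±0.02) therefore pass with large
margin. Against a genuinely 3D ground truth the same architecture would
carry the discretisation error instead.

The series network solves `Pa − Pv = Σ(R_in,i·Q + R_sl,i·Q²) + R_micro·Q`
via the cancellation-safe form of the positive quadratic root
(`Q = 2·drive/(b + √(b² + 4a·drive))`, exact also when `a = 0`). Pressures
are laid down segment-by-segment and interpolated linearly within segments.

## Virtual stenting and the planner

A stent is purely restored lumen: radii in the stented extent are replaced by
their reference values (no foreshortening, recoil or malapposition). The
planner calibrates segment coefficients once on the original geometry and
once on the fully idealized twin. Evaluating a plan swaps in the idealized
coefficients for lesion segments the stent covers (healthy segments are
unchanged by idealization and always reuse their coefficients); only a
partially covered lesion segment triggers a fresh two-solve calibration,
cached per stent extent. A plan evaluation after calibration is pure
arithmetic and completes in well under a millisecond. Plans are ranked by
predicted distal FFR, ties broken toward the shorter then more proximal
stent.

The post-PCI geometry of *untreated* lesions is assumed unchanged; in
reality a higher operating pressure can remodel them slightly, which this
model (like any anatomy-frozen planner) does not capture.

## Pullback, gradients and agreement statistics

The steady pullback trace is the FFR profile read distal→proximal. A
lesion's apparent gradient is the FFR step between reading points 2 mm
beyond its shoulders (far enough from post-stenotic flow disturbance; the
margin shrinks to half the gap, with a warning, if a companion lesion is
closer than twice the margin). Its true gradient repeats the reading after
all companions are idealized and the vessel re-solved. Discrepancies are
reported as `true − estimated` (positive = underestimation) together with
the relative error `100·|true − estimated|/true`.

`assess_cohort` produces: mean ± SD of paired differences, mean relative
error, Pearson r, Bland-Altman bias with 1.96·SD limits of agreement, a
two-tailed paired t test (scipy), and TOST equivalence (statsmodels
`ttost_paired`) at a ±0.02 FFR margin by default. Zero-variance differences
make the t statistics undefined and are reported as NaN.

## Synthetic cohort

Each vessel: length U(80, 140) mm, inlet radius U(1.4, 2.2) mm, linear taper
U(10, 30)%, two raised-cosine lesions with %DS U(40, 85) and length
U(8, 25) mm, separated by ≥ 10 mm of normal lumen and ≥ 5 mm from the vessel
ends, placed by rejection sampling; 0.25 mm sample spacing. Randomness is a
single PCG64 generator seeded with the `(seed, index)` pair per vessel, so
cohorts are bit-reproducible and order-independent. The generator emulates
anatomy only — no CT noise, segmentation error, eccentricity, bifurcations
or ectasia — so passing tests demonstrate the *modelling chain*, not
robustness to imaging artifacts.

## Problem sizes and numerical defaults

| Quantity | Default | Notes |
|---|---|---|
| working sample spacing | 0.25 mm | generator output |
| fine-grid spacing | 0.05 mm | halving it moves distal FFR < 0.002 |
| flow bracket / xtol | [1e−6, 50] mL/s / 1e−12 | Brent |
| flow_tol (fallback) | 0.05 mL/s | no published threshold exists |
| gradient margin | 2 mm | reading-point offset |
| TOST margin | 0.02 FFR | equivalence band |
| study sizes | 100 vessels (study), 80 (equivalence) | seconds of runtime |

The equivalence cohort of 80 and the study cohort of 100 vessels are the
package's standard experiment sizes; both complete in a few seconds, and all
quantities reported by `scripts/acceptance.py` are recomputed from these
seeded cohorts at run time.

## Known limitations

* Single conduit: no bifurcations or branch flow loss along the vessel.
* The expansion-loss law ignores lesion eccentricity, lesion-to-lesion
  turbulence coupling at very short gaps, and non-Newtonian rheology.
* The robust baseline fit assumes an approximately linear healthy taper.
* Microvascular function is a single resistance with a fixed hyperemic
  reduction; patient-level microvascular variability is not modelled.
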