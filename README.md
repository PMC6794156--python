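# ffrplan

Reduced-order coronary physiology for **serially diseased vessels**: hyperemic
FFR profiles from a lumen-radius profile, simulated pressure-wire pullback,
virtual stenting by lumen idealization, and prediction of the **true residual
FFR contribution** of the lesions left behind.

## The problem

Fractional flow reserve (FFR = Pd/Pa under maximal hyperemia) grades the
functional severity of a coronary stenosis. When two or more stenoses share
one vessel they interact: each lesion's resistance caps the hyperemic flow
the other sees, so the FFR step read across a lesion during pressure-wire
pullback *underestimates* the gradient that lesion would cause in isolation
(its FFR_true, revealed only after the companion is stented). Choosing which
lesion to treat from the pullback trace is therefore systematically biased —
and the bias grows as total vessel FFR falls.

`ffrplan` models this interplay and removes the bias non-invasively. A vessel
is a sampled radius profile `r(s)`; the pressure drop of any extent follows
the viscous + post-stenotic expansion-loss law

```
ΔP(Q) = R_v·Q + S·Q|Q|,   R_v = ∫ 8πμ/A(s)² ds,   S = (Kt·ρ/2)(1/A_min − 1/A_out)²
```

with lumen area `A = πr²`, blood viscosity μ and density ρ, and `Kt = 1.52`.
A fine-grid solver (the package's ground truth) couples this law to a
hyperemic microvascular boundary condition built from an allometric
resting-flow scaling (`Q_rest = q_scale·massᵏ`) and a fixed hyperemic
resistance reduction (default 0.24×).

The PCI planner works on a **flow-dependent resistance model**: each segment
(lesion or healthy stretch) is summarised as

```
R(Q) = R_in + R_sl·Q
```

calibrated from two whole-vessel solutions (hyperemia, and hyperemia with 40%
lower microvascular resistance); when the achieved flow difference is too
small, the coefficients fall back to the analytic 1D law. Virtually stenting
a lesion replaces its radii by the interpolated healthy reference ("percent
stenosis zero") and swaps in the idealized segment's coefficients; the series
network then re-solves in closed form, so exploring stent configurations is
effectively instantaneous after the one-time calibration.

Because no patient geometries ship with the package, a seeded synthetic
cohort generator produces tapering vessels with two raised-cosine stenoses
(40–85% diameter stenosis, ≥ 10 mm apart) whose hyperemic total-vessel FFR
spans a realistic serial-disease population.

## Worked example

Create a 110 mm vessel with a 50% lesion at 25–37 mm and a 62% lesion at
60–74 mm (`scripts/acceptance.py` and the test suite build such profiles
programmatically; any `s_mm,r_mm` CSV works):

```
$ ffrplan simulate --vessel example_vessel.csv
q = 1.6536 mL/s, distal FFR = 0.9055

$ ffrplan plan --vessel example_vessel.csv --stent-start 25 --stent-end 37
predicted distal FFR = 0.9197 (0.2 ms)
  residual gradient, lesion 1: 0.0715
```

Pre-PCI, the pullback reads an apparent gradient of 0.0696 across the distal
lesion. The planner predicts that once the proximal lesion is stented the
distal lesion will actually cost 0.0715 FFR — which is exactly what the
fine-grid re-solve of the stented geometry gives (0.0715). The pullback
underestimated the lesion; the planner did not.

The same comparison at cohort scale:

```
$ ffrplan experiment --n 20 --seed 1 --out out/
20 lesions on 20 vessels; total FFR 0.584 +/- 0.195
pullback error +0.0484 +/- 0.0656 (46.6%)
planner  error +0.0003 +/- 0.0008 (0.4%)
```

`error` is FFR_true − estimate per untreated lesion (positive =
underestimation), with the percent error expressed relative to the true
gradient. Full per-lesion tables and Bland-Altman/TOST agreement reports are
written as CSV/JSON.

## Command-line interface

`simulate`, `pullback`, `plan`, `cohort`, `experiment`, `config` — see
`ffrplan --help`. All physiology, fluid, solver and cohort parameters are
YAML-configurable (`ffrplan config --dump` prints the defaults).

## Not in scope

CT acquisition/segmentation, 3D CFD, bifurcating trees, pulsatile flow,
stent mechanics (recoil, malapposition), and pressure-signal artifacts.
See `docs/methods.md` for the model's assumptions and limitations.
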