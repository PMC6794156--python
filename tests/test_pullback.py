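"""Pullback simulation, per-lesion gradients and agreement statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from ffrplan import (
    BoundaryCondition,
    HemodynamicSolution,
    LesionSegment,
    PullbackTrace,
    apparent_gradient,
    assess_cohort,
    ffr_true_gradient,
    oracle_solve,
    simulate_pullback,
)

from conftest import make_vessel, true_lesions

BC = BoundaryCondition(pa=90.0, pv=0.0, r_micro=25.0)
TWO = [(25.0, 12.0, 0.55), (60.0, 14.0, 0.6)]


def _step_trace():
    """Synthetic serial-disease trace: 1.00 -> 0.93 -> 0.80 step profile."""
    s = np.linspace(0.0, 100.0, 401)
    ffr = np.interp(s, [0.0, 28.0, 40.0, 55.0, 70.0, 100.0],
                    [1.0, 1.0, 0.93, 0.93, 0.80, 0.80])
    return PullbackTrace(s=s[::-1].copy(), ffr=ffr[::-1].copy())


class TestSimulatePullback:
    def test_healthy_vessel_trace_is_near_flat(self, wide_healthy):
        trace = simulate_pullback(oracle_solve(wide_healthy, BC))
        assert trace.ffr.min() >= 0.97

    def test_trace_starts_distal_and_ends_at_unity(self):
        g = make_vessel(length=110.0, r0=2.0, lesions=TWO)
        trace = simulate_pullback(oracle_solve(g, BC))
        assert trace.s[0] > trace.s[-1]
        assert trace.ffr[-1] == pytest.approx(1.0, abs=1e-6)

    def test_step_downs_colocate_with_lesions(self):
        g = make_vessel(length=110.0, r0=2.0, lesions=TWO, ds=0.25)
        les = true_lesions(g, TWO)
        trace = simulate_pullback(oracle_solve(g, BC))
        for lesion in les:
            drop = apparent_gradient(trace, lesion, margin=0.25, lesions=les)
            assert drop > 0.02
        # healthy stretch between lesions carries almost no drop
        flat = trace.ffr_at(44.0) - trace.ffr_at(52.0)
        assert abs(flat) < 0.005


class TestApparentGradient:
    def test_reads_worked_step_profile(self):
        trace = _step_trace()
        l1 = LesionSegment(28.0, 40.0, 1.0, 2.0, 50.0)
        l2 = LesionSegment(55.0, 70.0, 1.0, 2.0, 50.0)
        assert apparent_gradient(trace, l1, margin=2.0) == pytest.approx(0.07, abs=1e-9)
        assert apparent_gradient(trace, l2, margin=2.0) == pytest.approx(0.13, abs=1e-9)

    def test_healthy_extent_has_negligible_gradient(self, wide_healthy):
        trace = simulate_pullback(oracle_solve(wide_healthy, BC))
        les = LesionSegment(30.0, 45.0, 2.5, 2.5, 0.0)
        assert apparent_gradient(trace, les) < 0.005

    def test_gradients_telescope_to_total_drop(self):
        g = make_vessel(length=110.0, r0=2.0, lesions=TWO)
        les = true_lesions(g, TWO)
        sol = oracle_solve(g, BC)
        trace = simulate_pullback(sol)
        g1 = apparent_gradient(trace, les[0], margin=0.0)
        g2 = apparent_gradient(trace, les[1], margin=0.0)
        healthy = ((trace.ffr_at(0.0) - trace.ffr_at(les[0].start_mm))
                   + (trace.ffr_at(les[0].end_mm) - trace.ffr_at(les[1].start_mm))
                   + (trace.ffr_at(les[1].end_mm) - trace.ffr_at(110.0)))
        assert g1 + g2 + healthy == pytest.approx(1.0 - sol.ffr_distal, abs=1e-9)

    def test_adjacent_lesion_shrinks_margin_with_warning(self):
        trace = _step_trace()
        l1 = LesionSegment(28.0, 40.0, 1.0, 2.0, 50.0)
        l2 = LesionSegment(43.0, 55.0, 1.0, 2.0, 50.0)  # 3 mm gap < 2*margin
        with pytest.warns(UserWarning, match="shrunk"):
            apparent_gradient(trace, l1, margin=2.0, lesions=[l1, l2])

    def test_never_negative(self):
        trace = _step_trace()
        les = LesionSegment(75.0, 95.0, 1.0, 2.0, 50.0)  # flat region
        assert apparent_gradient(trace, les) >= 0.0


class TestFfrTrueGradient:
    def test_single_lesion_equals_apparent_gradient(self):
        specs = [(35.0, 14.0, 0.6)]
        g = make_vessel(length=90.0, r0=2.0, lesions=specs)
        les = true_lesions(g, specs)
        trace = simulate_pullback(oracle_solve(g, BC))
        apparent = apparent_gradient(trace, les[0], lesions=les)
        assert ffr_true_gradient(g, les, les[0], BC) == pytest.approx(
            apparent, abs=1e-9)

    def test_serial_lesions_are_underestimated_by_pullback(self):
        g = make_vessel(length=110.0, r0=2.0, lesions=TWO)
        les = true_lesions(g, TWO)
        trace = simulate_pullback(oracle_solve(g, BC))
        for lesion in les:
            apparent = apparent_gradient(trace, lesion, lesions=les)
            assert ffr_true_gradient(g, les, lesion, BC) > apparent

    def test_vanishing_companion_recovers_apparent_gradient(self):
        gaps = []
        for companion_depth in (0.4, 0.25, 0.1, 0.03):
            specs = [(25.0, 12.0, companion_depth), (60.0, 14.0, 0.6)]
            g = make_vessel(length=110.0, r0=2.0, lesions=specs)
            les = true_lesions(g, specs)
            trace = simulate_pullback(oracle_solve(g, BC))
            apparent = apparent_gradient(trace, les[1], lesions=les)
            true = ffr_true_gradient(g, les, les[1], BC)
            gaps.append(true - apparent)
        assert all(a >= b - 1e-12 for a, b in zip(gaps[:-1], gaps[1:]))
        assert gaps[-1] < 0.005

    def test_target_must_be_member(self):
        g = make_vessel(length=110.0, r0=2.0, lesions=TWO)
        les = true_lesions(g, TWO)
        stranger = LesionSegment(5.0, 10.0, 1.0, 2.0, 50.0)
        with pytest.raises(ValueError):
            ffr_true_gradient(g, les, stranger, BC)


class TestAssessCohort:
    def test_perfect_agreement(self):
        rep = assess_cohort([(0.1, 0.1), (0.2, 0.2), (0.3, 0.3)])
        assert rep.mean_diff == 0.0
        assert rep.mean_relative_error_pct == 0.0
        assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_worked_relative_error_is_forty_percent(self):
        rep = assess_cohort([(0.06, 0.10), (0.12, 0.20)])
        assert rep.mean_relative_error_pct == pytest.approx(40.0, abs=1e-10)

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(42)
        true = rng.uniform(0.05, 0.3, size=40)
        est = true - rng.normal(0.02, 0.015, size=40)
        rep = assess_cohort(list(zip(est, true)), tost_margin=0.02)
        d = true - est
        n = d.size
        mean, sd = d.mean(), d.std(ddof=1)
        se = sd / np.sqrt(n)
        # paired t, two-tailed
        t = mean / se
        p_t = 2.0 * sps.t.sf(abs(t), n - 1)
        # Pearson from the definition
        ex, ey = est - est.mean(), true - true.mean()
        r = (ex * ey).sum() / np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
        # TOST: two one-sided paired t tests at +/- margin on est - true
        dd = est - true
        m, sdd = dd.mean(), dd.std(ddof=1)
        see = sdd / np.sqrt(n)
        p_lo = sps.t.sf((m - (-0.02)) / see, n - 1)
        p_hi = sps.t.cdf((m - 0.02) / see, n - 1)
        p_tost = max(p_lo, p_hi)
        assert rep.mean_diff == pytest.approx(mean, abs=1e-12)
        assert rep.sd_diff == pytest.approx(sd, abs=1e-12)
        assert rep.paired_t_p == pytest.approx(p_t, abs=1e-10)
        assert rep.pearson_r == pytest.approx(r, abs=1e-10)
        assert rep.tost_p == pytest.approx(p_tost, abs=1e-10)
        assert rep.bland_altman["lo"] == pytest.approx(mean - 1.96 * sd, abs=1e-12)
        assert rep.bland_altman["hi"] == pytest.approx(mean + 1.96 * sd, abs=1e-12)

    def test_zero_variance_nonzero_mean_reports_undefined_t(self):
        # differences are exactly representable, so the SD is exactly zero
        rep = assess_cohort([(0.125, 0.25), (0.5, 0.625)])
        assert np.isnan(rep.paired_t_p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            assess_cohort([(0.1, 0.2)])

    def test_nonpositive_true_gradient_rejected(self):
        with pytest.raises(ValueError):
            assess_cohort([(0.1, 0.0), (0.1, 0.2)])
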