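"""Geometry: resampling, reference lumen, stenosis grading, idealization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ffrplan import (
    GeometryError,
    LesionSegment,
    VesselGeometry,
    detect_lesions,
    idealize,
    percent_stenosis,
    read_vessel_csv,
    reference_profile,
    resample,
    segment_vessel,
    write_vessel_csv,
)
from ffrplan.geometry import lesions_from_json, lesions_to_json

from conftest import make_vessel, true_lesions


class TestVesselGeometry:
    def test_rejects_non_monotone_arclength(self):
        s = np.linspace(0, 10, 20)
        s[5] = s[7]
        with pytest.raises(GeometryError):
            VesselGeometry(s, np.full(20, 2.0))

    def test_rejects_nonpositive_radius(self):
        s = np.linspace(0, 10, 20)
        r = np.full(20, 2.0)
        r[3] = 0.0
        with pytest.raises(GeometryError):
            VesselGeometry(s, r)

    def test_rejects_too_few_samples(self):
        with pytest.raises(GeometryError):
            VesselGeometry(np.linspace(0, 10, 5), np.full(5, 2.0))


class TestResample:
    def test_constant_tube_is_exact(self, straight_tube):
        g = resample(straight_tube, 0.1)
        assert np.all(g.r == 1.5)
        assert g.s[0] == 0.0 and g.s[-1] == 30.0

    def test_idempotent(self, straight_tube):
        g1 = resample(straight_tube, 0.3)
        g2 = resample(g1, 0.3)
        assert np.array_equal(g1.s, g2.s)
        assert np.array_equal(g1.r, g2.r)

    def test_linear_taper_interpolates_linearly(self):
        g = make_vessel(length=50.0, r0=2.0, taper=0.25)  # 2.0 -> 1.5
        g2 = resample(g, 0.5)
        assert g2.radius_at(25.0) == pytest.approx(1.75, abs=1e-12)

    def test_rejects_nonpositive_ds(self, straight_tube):
        with pytest.raises(GeometryError):
            resample(straight_tube, 0.0)


class TestReferenceProfile:
    def test_identity_for_healthy_vessel(self, straight_tube):
        ref = reference_profile(straight_tube, [])
        assert np.array_equal(ref.r, straight_tube.r)

    def test_flat_flanks_give_flat_reference(self):
        specs = [(20.0, 10.0, 0.5)]
        g = make_vessel(length=60.0, r0=2.0, lesions=specs)
        ref = reference_profile(g, true_lesions(g, specs))
        assert np.allclose(ref.r, 2.0, atol=1e-12)

    def test_taper_reference_is_linear_interpolation(self):
        # disease-free taper 2.5 -> 1.5 over 100 mm; oracle: the taper itself
        specs = [(40.0, 20.0, 0.6)]
        g = make_vessel(length=100.0, r0=2.5, taper=0.4, lesions=specs)
        baseline = make_vessel(length=100.0, r0=2.5, taper=0.4)
        ref = reference_profile(g, true_lesions(g, specs))
        assert np.allclose(ref.r, baseline.r, atol=1e-12)

    def test_lesion_at_endpoint_raises(self):
        specs = [(0.0, 10.0, 0.5)]
        g = make_vessel(length=60.0, r0=2.0, lesions=specs)
        les = LesionSegment(0.0, 10.0, 1.0, 2.0, 50.0)
        with pytest.raises(GeometryError):
            reference_profile(g, [les])


class TestPercentStenosis:
    def test_uniform_tube_is_zero(self, straight_tube):
        assert percent_stenosis(straight_tube, (5.0, 25.0)) == pytest.approx(0.0, abs=0.1)

    def test_half_radius_is_fifty_percent(self):
        specs = [(20.0, 10.0, 0.5)]
        g = make_vessel(length=60.0, r0=2.0, lesions=specs)
        pct = percent_stenosis(g, (15.0, 35.0), true_lesions(g, specs))
        assert pct == pytest.approx(50.0, abs=0.5)

    def test_matches_independent_grid_scan(self):
        # brute-force oracle: evaluate the generator's closed-form profile on
        # the sample grid and grade the narrowing directly
        st_, ln, d = 20.0, 12.0, 0.6
        g = make_vessel(length=60.0, r0=2.0, lesions=[(st_, ln, d)], ds=0.25)
        s = g.s
        m = (s >= st_) & (s < st_ + ln)
        w = 0.5 * (1.0 - np.cos(2.0 * np.pi * (s[m] - st_) / ln))
        expected = 100.0 * d * w.max()   # reference radius is exactly 2.0
        assert percent_stenosis(g, (st_, st_ + ln)) == pytest.approx(expected, abs=0.1)

    def test_empty_extent_raises(self, straight_tube):
        with pytest.raises(GeometryError):
            percent_stenosis(straight_tube, (10.0, 10.0))

    def test_invariant_under_finer_resampling(self):
        g = make_vessel(length=80.0, r0=2.0, taper=0.2,
                        lesions=[(30.0, 15.0, 0.55)], ds=0.5)
        coarse = percent_stenosis(g, (25.0, 50.0))
        fine = percent_stenosis(resample(g, 0.1), (25.0, 50.0))
        assert abs(coarse - fine) < 1.0


class TestDetectLesions:
    def test_healthy_vessel_gives_empty_list(self, straight_tube):
        assert detect_lesions(straight_tube) == []

    def test_two_separated_lesions_stay_separate(self):
        specs = [(20.0, 10.0, 0.5), (60.0, 10.0, 0.5)]  # 30 mm apart
        g = make_vessel(length=100.0, r0=2.0, lesions=specs)
        found = detect_lesions(g, min_pct=30.0, min_gap=10.0)
        assert len(found) == 2

    def test_close_lesions_merge(self):
        specs = [(30.0, 10.0, 0.5), (45.0, 10.0, 0.5)]  # 5 mm apart
        g = make_vessel(length=100.0, r0=2.0, lesions=specs)
        found = detect_lesions(g, min_pct=30.0, min_gap=10.0)
        assert len(found) == 1
        assert found[0].start_mm < 31.0 and found[0].end_mm > 54.0

    def test_recovers_planted_extents_within_one_sample(self):
        ds = 0.25
        specs = [(22.3, 14.0, 0.55), (61.7, 18.0, 0.45)]
        g = make_vessel(length=110.0, r0=2.1, taper=0.2, lesions=specs, ds=ds)
        found = detect_lesions(g, min_pct=30.0, min_gap=8.0)
        assert len(found) == 2
        for les, (st_, ln, d) in zip(found, specs):
            assert abs(les.start_mm - st_) <= ds + 1e-9
            assert abs(les.end_mm - (st_ + ln)) <= ds + 1e-9
            assert les.pct_ds == pytest.approx(100.0 * d, abs=1.0)

    def test_invalid_min_pct_raises(self, straight_tube):
        with pytest.raises(GeometryError):
            detect_lesions(straight_tube, min_pct=0.0)


class TestIdealize:
    def test_healthy_vessel_unchanged(self, straight_tube):
        g = idealize(straight_tube, (5.0, 25.0), [])
        assert np.array_equal(g.r, straight_tube.r)

    def test_covered_lesion_has_zero_stenosis(self):
        specs = [(20.0, 10.0, 0.5)]
        g = make_vessel(length=60.0, r0=2.0, taper=0.15, lesions=specs)
        les = true_lesions(g, specs)
        g2 = idealize(g, (15.0, 35.0), les)
        assert percent_stenosis(g2, (15.0, 35.0)) == pytest.approx(0.0, abs=0.1)
        assert percent_stenosis(g2, (20.0, 28.0)) == pytest.approx(0.0, abs=0.1)

    def test_other_lesion_untouched_bitwise(self):
        specs = [(20.0, 10.0, 0.5), (50.0, 12.0, 0.6)]
        g = make_vessel(length=100.0, r0=2.0, lesions=specs)
        les = true_lesions(g, specs)
        g2 = idealize(g, les[0].extent, les)
        outside = ~g.sample_mask(*les[0].extent)
        assert np.array_equal(g2.r[outside], g.r[outside])

    def test_idempotent(self):
        specs = [(20.0, 10.0, 0.5)]
        g = make_vessel(length=60.0, r0=2.0, taper=0.1, lesions=specs)
        les = true_lesions(g, specs)
        g1 = idealize(g, (18.0, 34.0), les)
        g2 = idealize(g1, (18.0, 34.0), les)
        assert np.array_equal(g1.r, g2.r)


class TestSegmentVessel:
    def test_tiling_covers_vessel_without_overlap(self):
        specs = [(20.0, 10.0, 0.5), (50.0, 12.0, 0.6)]
        g = make_vessel(length=100.0, r0=2.0, lesions=specs)
        extents = segment_vessel(g, true_lesions(g, specs))
        assert extents[0][0] == g.s[0] and extents[-1][1] == g.s[-1]
        for a, b in zip(extents[:-1], extents[1:]):
            assert a[1] == b[0]

    def test_overlapping_lesions_raise(self):
        g = make_vessel(length=100.0, r0=2.0)
        l1 = LesionSegment(20.0, 40.0, 1.0, 2.0, 50.0)
        l2 = LesionSegment(30.0, 50.0, 1.0, 2.0, 50.0)
        with pytest.raises(GeometryError):
            segment_vessel(g, [l1, l2])


class TestIO:
    def test_csv_round_trip_is_exact(self, tmp_path):
        g = make_vessel(length=77.3, r0=1.9, taper=0.22,
                        lesions=[(30.0, 12.0, 0.5)], label="roundtrip")
        path = tmp_path / "v.csv"
        write_vessel_csv(g, path)
        g2 = read_vessel_csv(path)
        assert np.array_equal(g.s, g2.s)
        assert np.array_equal(g.r, g2.r)
        assert g2.label == "roundtrip"

    def test_malformed_header_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x_mm,y_mm\n0,2\n1,2\n")
        with pytest.raises(GeometryError):
            read_vessel_csv(path)

    def test_lesion_json_round_trip(self):
        les = [LesionSegment(20.0, 30.0, 1.0, 2.0, 50.0)]
        assert lesions_from_json(lesions_to_json(les)) == les


@given(depth=st.floats(0.35, 0.85), length=st.floats(8.0, 25.0),
       taper=st.floats(0.0, 0.3))
def test_reference_never_below_measured(depth, length, taper):
    """Narrowing-only geometry: reference >= measured radius everywhere."""
    specs = [(30.0, length, depth)]
    g = make_vessel(length=90.0, r0=2.0, taper=taper, lesions=specs)
    ref = reference_profile(g, true_lesions(g, specs))
    assert np.all(ref.r >= g.r - 1e-12)


@given(depth=st.floats(0.35, 0.8), taper=st.floats(0.0, 0.3))
def test_detect_then_idealize_removes_stenosis(depth, taper):
    """detect -> idealize round trip leaves no narrowing above tolerance."""
    g = make_vessel(length=90.0, r0=2.0, taper=taper,
                    lesions=[(35.0, 14.0, depth)])
    found = detect_lesions(g, min_pct=30.0)
    assert len(found) == 1
    g2 = idealize(g, found[0].extent, found)
    assert percent_stenosis(g2, found[0].extent) < 1.0
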