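"""Field synthesis, ROI reports, circular medians, lead angles and
phase errors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phasortacs as pt
from phasortacs.errors import ValidationError
from phasortacs.field_metrics import PhasorField
from phasortacs.phasor_optimize import wrap_deg


def brute_circular_median(angles):
    """Independent oracle: exhaustive search over observed angles for the
    minimiser of summed absolute circular deviations."""
    best_angle, best_cost = None, np.inf
    for c in angles:
        cost = sum(abs(wrap_deg(a - c)) for a in angles)
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12
            and (best_angle is None or wrap_deg(c) < best_angle)
        ):
            best_cost, best_angle = cost, wrap_deg(c)
    return best_angle


def montage_for(lf, returns):
    return pt.complete_montage(np.asarray(returns, dtype=complex), lf)


class TestSynthesizeField:
    def test_unit_real_current_gives_column(self, small_leadfield):
        x = np.zeros(6, dtype=complex)
        x[2] = 1.0
        f = pt.synthesize_field(small_leadfield, montage_for(small_leadfield, x))
        assert np.array_equal(f.values.real, small_leadfield.matrix[:, 2])
        assert np.all(f.values.imag == 0)

    def test_multiplying_by_j_rotates_phases_90(self, small_leadfield, rng):
        x = rng.normal(size=6) + 1j * rng.normal(size=6)
        f0 = pt.synthesize_field(small_leadfield, montage_for(small_leadfield, x))
        f1 = pt.synthesize_field(
            small_leadfield, montage_for(small_leadfield, 1j * x)
        )
        assert np.allclose(f1.amplitude, f0.amplitude)
        assert np.allclose(
            np.abs(wrap_deg(f1.phase_deg - f0.phase_deg - 90.0)), 0, atol=1e-9
        )

    def test_montage_sum_gives_field_sum(self, small_leadfield, rng):
        xa = rng.normal(size=6) + 1j * rng.normal(size=6)
        xb = rng.normal(size=6) + 1j * rng.normal(size=6)
        fa = pt.synthesize_field(small_leadfield, montage_for(small_leadfield, xa))
        fb = pt.synthesize_field(small_leadfield, montage_for(small_leadfield, xb))
        fab = pt.synthesize_field(
            small_leadfield, montage_for(small_leadfield, xa + xb)
        )
        assert np.allclose(fab.values, fa.values + fb.values, atol=1e-12)

    def test_order_mismatch_rejected(self, small_leadfield):
        m = pt.ComplexMontage("Fpz", ["X0", "X1"], np.zeros(2, dtype=complex))
        with pytest.raises(ValidationError):
            pt.synthesize_field(small_leadfield, m)


class TestRoiReport:
    def test_uniform_field(self):
        f = PhasorField(np.full(10, 0.3 * np.exp(1j * np.deg2rad(45.0))))
        roi = pt.RoiPatch("r", np.arange(10))
        rep = pt.roi_report(f, roi)
        assert rep.e_max == pytest.approx(0.3)
        assert set(rep.halfmax_elements) == set(range(10))
        assert rep.median_phase_deg == pytest.approx(45.0)

    def test_halfmax_threshold(self):
        f = PhasorField(np.array([1.0, 0.6, 0.4], dtype=complex))
        rep = pt.roi_report(f, pt.RoiPatch("r", [0, 1, 2]))
        assert set(rep.halfmax_elements) == {0, 1}

    def test_zero_field_flags_undefined_phase(self):
        f = PhasorField(np.zeros(5, dtype=complex))
        rep = pt.roi_report(f, pt.RoiPatch("r", [0, 1]))
        assert rep.e_max == 0
        assert not rep.phase_defined

    def test_wraparound_median_stays_near_170(self, rng):
        phases = 170.0 + 8.0 * rng.standard_normal(1000)  # wraps past 180
        f = PhasorField(np.exp(1j * np.deg2rad(phases)))
        rep = pt.roi_report(f, pt.RoiPatch("r", np.arange(1000)))
        assert abs(wrap_deg(rep.median_phase_deg - 170.0)) < 2.0
        # with an even count the two central order statistics tie in
        # cost; accept either side of the flat segment
        assert rep.median_phase_deg == pytest.approx(
            brute_circular_median(f.phase_deg), abs=0.1
        )


class TestCircularMedian:
    def test_matches_bruteforce_on_random_sets(self, rng):
        for _ in range(200):
            n = rng.integers(3, 25)
            angles = wrap_deg(rng.uniform(-180, 180, size=n))
            assert pt.circular_median(angles) == pytest.approx(
                brute_circular_median(angles), abs=1e-9
            )

    def test_equals_linear_median_for_concentrated_data(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30)) | 1  # odd, unique linear median
            center = rng.uniform(-100, 100)
            angles = center + rng.uniform(-80, 80, size=n)
            assert pt.circular_median(angles) == pytest.approx(
                float(np.median(angles)), abs=1e-9
            )


class TestLeadAngleAndError:
    @pytest.mark.parametrize(
        "ref,other,expected",
        [
            (2.92, 117.20, 114.28),  # lateral parietal leads frontal eye field
            (0.03, 90.21, 90.18),  # left auditory leads right auditory
            (-3.11, -57.34, -54.23),  # three-ROI montage, frontal eye field
            (-3.11, 135.00, 138.11),  # three-ROI montage, prefrontal
        ],
    )
    def test_reported_simulation_deltas(self, ref, other, expected):
        assert pt.lead_angle(ref, other) == pytest.approx(expected, abs=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        for a, b in rng.uniform(-179, 179, size=(100, 2)):
            assert pt.lead_angle(a, b) == pytest.approx(
                -pt.lead_angle(b, a), abs=1e-9
            )

    def test_undefined_phase_rejected(self):
        rep = pt.RoiReport("r", 0.0, np.empty(0, dtype=np.int64),
                           float("nan"), phase_defined=False)
        with pytest.raises(ValidationError):
            pt.lead_angle(rep, 10.0)

    @pytest.mark.parametrize(
        "achieved,desired,exp_abs,exp_rel",
        [
            (114.28, 120.0, 5.72, 5.72 / 120 * 100),
            (90.97, 90.0, 0.97, 0.97 / 90 * 100),  # rounds to 1.1%
            (87.55, 90.0, 2.45, 2.45 / 90 * 100),  # rounds to 2.7%
            (45.0, 45.0, 0.0, 0.0),
        ],
    )
    def test_phase_error_values(self, achieved, desired, exp_abs, exp_rel):
        ab, rel = pt.phase_error(achieved, desired)
        assert ab == pytest.approx(exp_abs, abs=1e-9)
        assert rel == pytest.approx(exp_rel, abs=1e-9)

    def test_table_relative_errors_round_to_printed_values(self):
        assert round(pt.phase_error(90.97, 90.0)[1], 1) == 1.1
        assert round(pt.phase_error(87.55, 90.0)[1], 1) == 2.7

    def test_zero_desired_small_error_is_zero_relative(self):
        ab, rel = pt.phase_error(0.4, 0.0)
        assert ab == pytest.approx(0.4)
        assert rel == 0.0

    def test_zero_desired_large_error_flagged(self):
        _, rel = pt.phase_error(30.0, 0.0)
        assert np.isnan(rel)


class TestMetricInvariances:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(c=st.floats(0.1, 50.0))
    def test_real_scaling_preserves_all_phase_metrics(self, c):
        rng = np.random.default_rng(11)
        lf = pt.LeadField(rng.normal(size=(40, 5)), "A",
                          [f"R{i}" for i in range(5)], np.ones(40))
        x = rng.normal(size=5) + 1j * rng.normal(size=5)
        roi_a = pt.RoiPatch("a", np.arange(0, 15))
        roi_b = pt.RoiPatch("b", np.arange(20, 35))
        m0 = montage_for(lf, x)
        m1 = montage_for(lf, c * x)
        f0, f1 = pt.synthesize_field(lf, m0), pt.synthesize_field(lf, m1)
        for roi in (roi_a, roi_b):
            r0, r1 = pt.roi_report(f0, roi), pt.roi_report(f1, roi)
            assert r1.e_max == pytest.approx(c * r0.e_max, rel=1e-12)
            assert np.array_equal(r1.halfmax_elements, r0.halfmax_elements)
            assert r1.median_phase_deg == pytest.approx(
                r0.median_phase_deg, abs=1e-9
            )

    def test_wrap_deg_range_and_idempotence(self):
        vals = np.array([-720, -180.0, -179.999, 0, 179.999, 180.0, 540.0])
        w = wrap_deg(vals)
        assert np.all((w > -180.0) & (w <= 180.0))
        assert np.allclose(wrap_deg(w), w)
        assert wrap_deg(-180.0) == 180.0
        assert wrap_deg(540.0) == 180.0
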