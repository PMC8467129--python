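"""Fringe-period estimation and two-step frequency calibration."""

import numpy as np
import pytest

from sfdikit.freqcal import (
    DEFAULT_FREQUENCIES,
    CheckerboardScale,
    calibratable_frequencies,
    camera_to_actual_period,
    estimate_pixel_period,
    extrapolate_rrp,
    period_percentage_error,
    period_ratio,
    projection_period_for_target,
    two_step_calibration,
)
from sfdikit.synthetic import simulate_fringe_profile

SCALE = CheckerboardScale(xr=5.0, xc_mean=78.3)


class TestEstimatePixelPeriod:
    def test_recovers_known_cosine_period(self):
        profile = simulate_fringe_profile(158.2, length=1000)
        assert estimate_pixel_period(profile) == pytest.approx(158.2, abs=0.5)

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_pixel_period(np.full(500, 0.7))

    def test_single_period_rejected(self):
        profile = simulate_fringe_profile(400.0, length=500)
        with pytest.raises(ValueError, match="minima"):
            estimate_pixel_period(profile)

    def test_amplitude_scale_invariance(self):
        profile = simulate_fringe_profile(90.0, length=800)
        assert estimate_pixel_period(5.0 * profile) == pytest.approx(
            estimate_pixel_period(profile), rel=1e-12
        )


class TestPeriodChain:
    def test_rig_worked_example(self):
        """Tc = 158.2 px with a 5 mm checkerboard at 78.3 px/cell gives the
        plane period 10.1 mm and a period ratio of 3960 px/m for Tp = 40."""
        tr = camera_to_actual_period(158.2, SCALE)
        assert round(tr, 1) == 10.1
        rrp = period_ratio(40.0, tr)
        assert round(rrp * 1000) == 3960

    def test_one_cell_period_maps_to_cell_length(self):
        assert camera_to_actual_period(SCALE.xc_mean, SCALE) == pytest.approx(SCALE.xr)

    def test_linearity_and_round_trip(self):
        tr = camera_to_actual_period(100.0, SCALE)
        assert camera_to_actual_period(200.0, SCALE) == pytest.approx(2 * tr)
        rrp = period_ratio(37.0, tr)
        assert rrp * tr == pytest.approx(37.0)

    def test_projection_period_for_target(self):
        # rrp = 3.96 px/mm, fx = 0.14 mm^-1 -> Tre = 7.143 mm -> Tp ~ 28.3 px
        tp = projection_period_for_target(1.0 / 0.14, 3.96)
        assert tp == pytest.approx(28.3, abs=0.05)

    def test_unrepresentable_period_rejected(self):
        with pytest.raises(ValueError, match="unrepresentable"):
            projection_period_for_target(0.1, 3.96)

    @pytest.mark.parametrize(
        "tre, tv, expected", [(10.0, 10.0, 0.0), (10.0, 9.8, 2.0), (10.0, 10.2, 2.0)]
    )
    def test_percentage_error(self, tre, tv, expected):
        assert period_percentage_error(tre, tv) == pytest.approx(expected)


class TestCalibratableFrequencies:
    def test_reference_list_under_analysis_field(self):
        """With a 140 mm analysis window inset from the 150 mm whiteboard,
        exactly the nine frequencies strictly above 0.014 mm^-1 span two
        full periods and can be measured."""
        cal = calibratable_frequencies(DEFAULT_FREQUENCIES, fov_mm=140.0)
        assert len(cal) == 9
        assert min(cal) == pytest.approx(0.028)

    def test_sixteen_reference_frequencies_packaged(self):
        assert len(DEFAULT_FREQUENCIES) == 16
        assert DEFAULT_FREQUENCIES[0] == 0.0 and DEFAULT_FREQUENCIES[-1] == 0.14


def _biased_measure(rrp_true, bias):
    """Simulated measurement: realised plane period carries the bias; the
    returned Tv passes through fringe rendering and period estimation."""

    def measure(tp_px):
        tc = tp_px / rrp_true * bias * SCALE.xc_mean / SCALE.xr
        profile = simulate_fringe_profile(tc, length=max(1000, int(3.2 * tc)))
        return camera_to_actual_period(estimate_pixel_period(profile), SCALE)

    return measure


class TestTwoStepCalibration:
    TARGETS = [1.0 / f for f in calibratable_frequencies(DEFAULT_FREQUENCIES, fov_mm=140.0)]
    RRP0 = period_ratio(40.0, camera_to_actual_period(158.2, SCALE))

    def test_unbiased_system_is_a_fixed_point(self):
        res = two_step_calibration(self.RRP0, self.TARGETS, _biased_measure(self.RRP0, 1.0))
        assert res.step1_mean_error < 0.2
        assert res.step2_mean_error < 0.2

    def test_multiplicative_bias_removed_in_one_update(self):
        """A 2% period bias gives ~2% step-1 error and collapses below 0.2%
        after the per-frequency ratio update."""
        res = two_step_calibration(self.RRP0, self.TARGETS, _biased_measure(self.RRP0, 1.02))
        assert res.step1_mean_error == pytest.approx(2.0, abs=0.3)
        assert res.step2_mean_error < 0.2
        assert res.step2_mean_error <= res.step1_mean_error

    def test_failed_frequency_flagged_others_proceed(self):
        calls = {"n": 0}
        good = _biased_measure(self.RRP0, 1.0)

        def flaky(tp):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("detector glitch")
            return good(tp)

        res = two_step_calibration(self.RRP0, self.TARGETS[:4], flaky)
        flagged = [r.flagged for r in res.step1]
        assert flagged == [False, True, False, False]
        assert np.isfinite(res.step1_mean_error)

    def test_extrapolation_needs_two_points(self):
        with pytest.raises(ValueError):
            extrapolate_rrp([0.028], [3.9], [0.007])
        out = extrapolate_rrp([0.028, 0.14], [3.9, 4.0], [0.007])
        assert np.isfinite(out).all()
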