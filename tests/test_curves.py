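"""Unit and property tests for single-curve parameter extraction."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfcmr.curves import (
    LV_BLOOD_POOL,
    MYOCARDIAL_SEGMENT,
    PerfusionParams,
    SignalTimeCurve,
    TruncatedPeakWarning,
    detect_lv_arrival,
    lv_reference_params,
    max_upslope,
    myocardial_params,
    peak,
    relative_params,
    seconds_to_beats,
    subtract_baseline,
    time_to_fraction,
)
from perfcmr.errors import (
    DegenerateReferenceError,
    InconsistentInputError,
    InvalidCurveError,
    NoEnhancementError,
)
from perfcmr.simulate import BolusModel, gamma_variate, simulate_curve

from conftest import make_curve


def brute_force_max_upslope(curve, window):
    """Independent oracle: enumerate every admissible window, fit with
    numpy.polyfit, keep the steepest slope (earliest start on ties)."""
    start_min = max(0, curve.n_baseline - (window - 1))
    best_slope, best_start = -np.inf, None
    for s in range(start_min, len(curve) - window + 1):
        slope = np.polyfit(curve.times[s : s + window], curve.si[s : s + window], 1)[0]
        if slope > best_slope:
            best_slope, best_start = slope, s
    return best_slope, best_start


class TestSubtractBaseline:
    def test_exact_mean_removed(self):
        c = make_curve([100, 100, 100, 150, 300, 310, 320, 330], n_baseline=3)
        out = subtract_baseline(c)
        assert np.allclose(out.si[:5], [0, 0, 0, 50, 200])
        assert np.array_equal(out.times, c.times)

    def test_constant_curve_goes_to_zero(self):
        c = make_curve([7.5] * 10, n_baseline=4)
        assert np.allclose(subtract_baseline(c).si, 0.0)

    def test_noisy_baseline_hand_arithmetic(self):
        c = make_curve([98, 102, 100, 180, 260, 270, 280, 290], n_baseline=3)
        out = subtract_baseline(c)
        assert np.allclose(out.si[:5], [-2, 2, 0, 80, 160])

    def test_idempotent(self):
        c = make_curve([98, 102, 100, 180, 260, 270, 280, 290], n_baseline=3)
        once = subtract_baseline(c)
        twice = subtract_baseline(once)
        assert np.allclose(once.si, twice.si)

    def test_too_few_baseline_frames_rejected(self):
        with pytest.raises(InvalidCurveError):
            make_curve([1, 2, 3, 4, 5, 6, 7], n_baseline=1)


class TestArrivalDetection:
    def test_noise_free_first_positive_frame(self):
        times = np.arange(8) * 0.8
        c = make_curve([0, 0, 0, 5, 40, 80, 90, 85], times=times, n_baseline=3)
        res = detect_lv_arrival(c)
        assert res.index == 3
        assert res.time == pytest.approx(2.4)

    def test_single_frame_spike_rejected(self):
        c = make_curve([0, 0, 0, 9, 0, 0, 30, 60, 80, 70], n_baseline=3)
        res = detect_lv_arrival(c)
        assert res.index == 6  # spike at frame 3 not confirmed by successor

    def test_threshold_walk_with_noisy_baseline(self):
        # baseline [-1, 1, 0]: mean 0, SD 1; k=3 -> threshold 3.
        # first frame > 3 whose successor also exceeds 3 is the SI-4 frame.
        c = make_curve([-1, 1, 0, 2, 4, 40, 45, 50], n_baseline=3)
        res = detect_lv_arrival(c, k_sigma=3.0)
        assert res.index == 4

    def test_no_enhancement_raises(self):
        c = make_curve([0, 0, 0, 0, 0, 0, 0, 0], n_baseline=3)
        with pytest.raises(NoEnhancementError):
            detect_lv_arrival(c)


class TestMaxUpslope:
    def test_exact_line(self):
        c = make_curve([0, 1, 2, 3, 4, 5, 6], n_baseline=2)
        res = max_upslope(c, window=5)
        assert res.slope == pytest.approx(1.0)

    def test_three_frame_windows_hand_enumerated(self):
        c = make_curve([0, 0, 1, 3, 6, 10, 10, 10], n_baseline=2)
        res = max_upslope(c, window=3)
        assert res.slope == pytest.approx(3.5)
        assert res.start_index == 3

    def test_constant_curve_zero_slope(self):
        c = make_curve([5.0] * 9, n_baseline=2)
        assert max_upslope(c, window=5).slope == pytest.approx(0.0)

    def test_window_cannot_lie_inside_baseline(self):
        # a steep artefact entirely inside the baseline must not win
        si = [0, 50, 0, 0, 0, 0, 2, 4, 6, 8]
        c = make_curve(si, n_baseline=5)
        res = max_upslope(c, window=3)
        assert res.start_index >= c.n_baseline - 2

    def test_shorter_than_window_raises(self):
        c = make_curve([0, 0, 1, 2, 3, 4, 5], n_baseline=2)
        with pytest.raises(InvalidCurveError):
            max_upslope(c, window=10)

    def test_matches_bruteforce_oracle_on_random_curves(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(9, 40))
            nb = int(rng.integers(2, 5))
            times = np.cumsum(rng.uniform(0.5, 1.2, size=n))
            si = np.concatenate(
                [rng.normal(0, 1, nb), np.cumsum(rng.uniform(-1, 4, n - nb))]
            )
            c = SignalTimeCurve("r", MYOCARDIAL_SEGMENT, times, si, nb)
            for window in (3, 5):
                got = max_upslope(c, window=window)
                want_slope, want_start = brute_force_max_upslope(c, window)
                assert got.slope == pytest.approx(want_slope, abs=1e-9)
                assert got.start_index == want_start

    def test_anchored_mode_fits_window_at_foot(self):
        c = make_curve([0, 0, 1, 3, 6, 10, 10, 10], n_baseline=2)
        res = max_upslope(c, window=3, mode="anchored", arrival_index=2)
        assert res.slope == pytest.approx(2.5)  # window (1, 3, 6)


class TestPeak:
    def test_simple_peak(self):
        times = np.arange(7) * 0.8
        c = make_curve([0, 0, 50, 200, 180, 190, 170], times=times, n_baseline=2)
        res = peak(c)
        assert res.value == pytest.approx(200)
        assert res.time == pytest.approx(2.4)
        assert not res.truncated

    def test_tie_takes_earliest_frame(self):
        c = make_curve([0, 0, 10, 200, 150, 200, 100, 90], n_baseline=2)
        assert peak(c).index == 3

    def test_monotone_curve_flagged_truncated(self):
        c = make_curve([0, 0, 10, 20, 30, 40, 50, 60], n_baseline=2)
        with pytest.warns(TruncatedPeakWarning):
            res = peak(c)
        assert res.truncated and res.index == 7

    def test_first_pass_end_limits_search(self):
        c = make_curve([0, 0, 10, 100, 80, 60, 300, 310], n_baseline=2)
        res = peak(c, first_pass_end=6)  # exclude the recirculation frames
        assert res.value == pytest.approx(100)


class TestTimeToFraction:
    def _curve(self):
        si = [0, 0, 0, 10, 30, 50, 80, 120, 180, 200, 190]
        return make_curve(si, n_baseline=3)

    def test_crossing_at_frame(self):
        si = [0, 0, 0, 20, 60, 100, 150, 200, 190, 180]
        c = make_curve(si, n_baseline=3)  # 50% of 200 hit exactly at t=5
        assert time_to_fraction(c, arrival_time=1.5) == pytest.approx(3.5)

    def test_linear_interpolation_between_frames(self):
        # straddle: (t=6, SI=80) and (t=7, SI=120), peak 200 -> t* = 6.5
        assert time_to_fraction(self._curve(), arrival_time=1.5) == pytest.approx(5.0)

    def test_fraction_one_is_frame_snapped_tmax(self):
        c = self._curve()
        t_peak = peak(c).time
        assert time_to_fraction(c, arrival_time=1.5, fraction=1.0) == pytest.approx(
            t_peak - 1.5
        )

    def test_frame_snapped_mode(self):
        got = time_to_fraction(self._curve(), arrival_time=1.5, interpolate=False)
        assert got == pytest.approx(7.0 - 1.5)

    def test_arrival_after_peak_raises(self):
        with pytest.raises(InconsistentInputError):
            time_to_fraction(self._curve(), arrival_time=99.0)

    def test_t50_never_exceeds_tmax(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            model = BolusModel(
                t0=4.0, amplitude=rng.uniform(10, 50),
                alpha=rng.uniform(2, 8), beta=rng.uniform(0.5, 3),
            )
            c = simulate_curve(model, hr=75, n_frames=45, n_baseline=3,
                               noise_sd=0.3, rng=rng)
            c = subtract_baseline(c)
            t50 = time_to_fraction(c, arrival_time=2.0, fraction=0.5)
            tmax = time_to_fraction(c, arrival_time=2.0, fraction=1.0)
            assert t50 <= tmax + 1e-12


class TestRelativeAndBeats:
    def _params(self, upslope, simax):
        return PerfusionParams(roi_id="x", roi_kind=MYOCARDIAL_SEGMENT,
                               upslope_abs=upslope, si_max_abs=simax)

    def test_percent_of_lv(self):
        lv = PerfusionParams("LV", LV_BLOOD_POOL, upslope_abs=25.0, si_max_abs=100.0)
        out = relative_params(self._params(4.5, 20.0), lv)
        assert out.rel_si_max == pytest.approx(20.0)
        assert out.rel_upslope == pytest.approx(18.0)

    def test_nonpositive_reference_rejected(self):
        lv = PerfusionParams("LV", LV_BLOOD_POOL, upslope_abs=0.0, si_max_abs=100.0)
        with pytest.raises(DegenerateReferenceError):
            relative_params(self._params(4.5, 20.0), lv)

    @given(c=st.floats(0.01, 100.0))
    def test_ratio_invariant_under_common_scaling(self, c):
        lv = PerfusionParams("LV", LV_BLOOD_POOL, upslope_abs=25.0 * c, si_max_abs=100.0 * c)
        out = relative_params(self._params(4.5 * c, 20.0 * c), lv)
        assert out.rel_upslope == pytest.approx(18.0)
        assert out.rel_si_max == pytest.approx(20.0)

    def test_seconds_to_beats(self):
        assert seconds_to_beats(60.0, 60.0) == pytest.approx(60.0)
        assert seconds_to_beats(0.0, 123.0) == 0.0
        assert seconds_to_beats(7.2, 77.0) == pytest.approx(9.24)
        with pytest.raises(ValueError):
            seconds_to_beats(-1.0, 60.0)


def _noise_free_pair(rng=None, lv_shift=0.0, myo_shift=0.0, scale=1.0):
    """Matching LV + myocardial noise-free curves on a 0.8 s grid."""
    rng = rng or np.random.default_rng(0)
    # feet deliberately off the 0.8 s sampling grid so frame membership is
    # unambiguous under whole-frame shifts
    lv_model = BolusModel(t0=4.1 + lv_shift, amplitude=100 * scale, alpha=3, beta=1.6)
    myo_model = BolusModel(t0=6.05 + myo_shift, amplitude=25 * scale, alpha=6, beta=1.5)
    lv = simulate_curve(lv_model, hr=75, n_frames=45, n_baseline=3, noise_sd=0,
                        rng=rng, roi_id="LV", roi_kind=LV_BLOOD_POOL)
    myo = simulate_curve(myo_model, hr=75, n_frames=45, n_baseline=3, noise_sd=0,
                         rng=rng, roi_id="seg01")
    return lv, myo


class TestEndToEndInvariances:
    def test_scale_invariance(self):
        lv1, myo1 = _noise_free_pair(scale=1.0)
        lv2, myo2 = _noise_free_pair(scale=3.7)
        p_lv1, p_lv2 = lv_reference_params(lv1), lv_reference_params(lv2)
        p1 = myocardial_params(myo1, p_lv1, hr=75)
        p2 = myocardial_params(myo2, p_lv2, hr=75)
        assert p2.upslope_abs == pytest.approx(3.7 * p1.upslope_abs)
        assert p2.si_max_abs == pytest.approx(3.7 * p1.si_max_abs)
        for f in ("rel_upslope", "rel_si_max", "t50", "tmax", "t50_beats", "tmax_beats"):
            assert getattr(p2, f) == pytest.approx(getattr(p1, f), rel=1e-9)

    def test_time_shift_invariance(self):
        # delay both curves by two whole frames: t50/tmax must not move
        rr = 60 / 75
        lv1, myo1 = _noise_free_pair()
        lv2, myo2 = _noise_free_pair(lv_shift=2 * rr, myo_shift=2 * rr)
        p1 = myocardial_params(myo1, lv_reference_params(lv1), hr=75)
        p2 = myocardial_params(myo2, lv_reference_params(lv2), hr=75)
        assert p2.t50 == pytest.approx(p1.t50, abs=1e-9)
        assert p2.tmax == pytest.approx(p1.tmax, abs=1e-9)

    def test_peak_time_recovered_within_half_rr(self):
        model = BolusModel(t0=4.0, amplitude=30, alpha=6, beta=1.5)
        rng = np.random.default_rng(1)
        c = simulate_curve(model, hr=75, n_frames=45, n_baseline=3, noise_sd=0, rng=rng)
        res = peak(subtract_baseline(c))
        assert abs(res.time - model.peak_time) <= (60 / 75) / 2
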