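"""Derived-variable formulas: sway ratios, symmetry angle, MAD%, RTD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fallrisk as fr
from fallrisk import TorqueTrace


class TestSymmetryAngle:
    @pytest.mark.parametrize(
        "left,right,expected",
        [
            (1.0, 1.0, 0.0),
            (0.0, 1.0, 50.0),
            (1.0, 0.0, 50.0),  # arctan limit handled as 90 degrees
            (60.0, 40.0, abs(45 - np.degrees(np.arctan(1.5))) / 90 * 100),
        ],
    )
    def test_values(self, left, right, expected):
        assert fr.symmetry_angle(left, right) == pytest.approx(expected, abs=1e-9)

    def test_worked_example_value(self):
        assert fr.symmetry_angle(60, 40) == pytest.approx(12.5666, abs=1e-3)

    @given(
        st.floats(0.01, 1e3, allow_nan=False),
        st.floats(0.01, 1e3, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_order_invariant(self, a, b):
        assert fr.symmetry_angle(a, b) == pytest.approx(fr.symmetry_angle(b, a), abs=1e-9)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            fr.symmetry_angle(0.0, 0.0)


class TestSwayRatios:
    def test_romberg(self):
        assert fr.romberg_ratio(2.0, 1.0) == 2.0
        assert fr.romberg_ratio(1.3, 1.3) == 1.0
        assert fr.romberg_ratio(0.5, 0.4) == pytest.approx(1.25)
        with pytest.raises(ValueError):
            fr.romberg_ratio(1.0, 0.0)

    def test_somatosensory(self):
        assert fr.somatosensory_ratio(4.0, 1.0) == 4.0
        assert fr.somatosensory_ratio(2.2, 2.2) == 1.0
        with pytest.raises(ValueError):
            fr.somatosensory_ratio(1.0, 0.0)

    def test_gait_speed_reserve(self):
        assert fr.gait_speed_reserve(1.5, 1.5) == 1.0
        assert fr.gait_speed_reserve(1.5, 1.2) == pytest.approx(1.25)
        with pytest.raises(ValueError):
            fr.gait_speed_reserve(1.0, 0.0)


class TestMadPercent:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([3, 3, 3, 3, 3], 0.0),
            # median 12, abs deviations {2,0,1,1,2}, MAD 1 -> 1/12*100
            ([10, 12, 11, 13, 14], 100.0 / 12.0),
            # even count: median 4.5, MAD 0.5 -> 0.5/4.5*100
            ([2, 4, 4, 4, 5, 5, 7, 9], 100.0 / 9.0),
        ],
    )
    def test_values(self, series, expected):
        assert fr.mad_percent(series) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(0.1, 100.0, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariant(self, c):
        s = [10, 12, 11, 13, 14]
        scaled = [c * v for v in s]
        assert fr.mad_percent(scaled) == pytest.approx(fr.mad_percent(s), rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            fr.mad_percent([1.0])
        with pytest.raises(ValueError):
            fr.mad_percent([-1.0, 0.0, 1.0])  # zero median


def ramp_trace(rate=2000.0, baseline=2.0, slope=100.0, rest_s=0.5, rise_s=0.5):
    """Rest at `baseline` Nm then a linear ramp of `slope` Nm/s."""
    n_rest = int(rest_s * rate)
    n_rise = int(rise_s * rate)
    t = np.arange(n_rise) / rate
    samples = np.concatenate([np.full(n_rest, baseline), baseline + slope * t])
    return TorqueTrace(samples, rate=rate)


class TestButterworth:
    def test_dc_gain_one(self):
        t = TorqueTrace(np.full(4000, 7.0), rate=2000.0)
        out = fr.butterworth_lowpass(t, cutoff=150.0)
        assert np.allclose(out.samples, 7.0, atol=1e-9)
        assert len(out) == len(t)

    def test_high_frequency_attenuated(self):
        rate = 2000.0
        tt = np.arange(8000) / rate
        sine = np.sin(2 * np.pi * 800.0 * tt)  # far above the 150 Hz cutoff
        out = fr.butterworth_lowpass(TorqueTrace(sine, rate=rate), cutoff=150.0)
        mid = out.samples[2000:6000]
        assert np.abs(mid).max() < 0.1  # >90% amplitude attenuation

    def test_double_filtering_attenuates_further(self):
        rate = 2000.0
        tt = np.arange(8000) / rate
        sine = np.sin(2 * np.pi * 300.0 * tt)
        once = fr.butterworth_lowpass(TorqueTrace(sine, rate=rate), cutoff=150.0)
        twice = fr.butterworth_lowpass(once, cutoff=150.0)
        assert np.abs(twice.samples[2000:6000]).max() <= np.abs(
            once.samples[2000:6000]
        ).max() + 1e-12

    def test_cutoff_at_or_above_nyquist_rejected(self):
        t = TorqueTrace(np.zeros(100), rate=2000.0)
        with pytest.raises(ValueError):
            fr.butterworth_lowpass(t, cutoff=2000.0)


class TestOnsetAndRtd:
    def test_onset_at_known_crossing(self):
        t = ramp_trace()  # baseline 2 Nm, +100 Nm/s after 1000 samples
        # reaches 2 + 4 Nm at 40 ms into the ramp = sample 1080
        assert fr.detect_onset(t, delta=4.0) == 1080

    def test_flat_trace_rejected(self):
        t = TorqueTrace(np.full(2000, 2.0), rate=2000.0)
        with pytest.raises(ValueError):
            fr.detect_onset(t)

    def test_trace_starting_above_threshold(self):
        samples = np.full(2000, 50.0)
        samples[:100] = 0.0  # baseline window average stays low
        t = TorqueTrace(samples, rate=2000.0, baseline_window=100)
        assert fr.detect_onset(t) == 100

    def test_linear_ramp_rtd(self):
        t = ramp_trace(slope=100.0)
        assert fr.rtd(t) == pytest.approx([100.0, 100.0, 100.0], rel=1e-6)

    def test_plateau_piecewise(self):
        # 100 Nm/s ramp that plateaus 60 ms after onset
        rate = 2000.0
        onset_val, slope = 2.0, 100.0
        rest = np.full(1000, onset_val)
        tt = np.arange(2000) / rate
        rise = onset_val + np.minimum(slope * tt, slope * 0.1)  # caps at +10 Nm (100 ms)
        t = TorqueTrace(np.concatenate([rest, rise]), rate=rate)
        onset = fr.detect_onset(t, delta=4.0)
        vals = fr.rtd(t, windows=((0, 50), (0, 100)))
        # onset is where torque = 6 Nm (40 ms into ramp); plateau at 100 ms
        # 0-50 ms window is fully on the ramp; 0-100 ms spans ramp then plateau
        assert vals[0] == pytest.approx(100.0, rel=1e-6)
        assert vals[1] == pytest.approx(60.0, rel=1e-6)

    def test_affine_trace_slope_independent_of_threshold(self):
        t = ramp_trace(slope=80.0, rise_s=1.0)
        for delta in (2.0, 4.0, 10.0):
            assert fr.rtd(t, delta=delta) == pytest.approx([80.0] * 3, rel=1e-6)

    def test_short_trace_rejected(self):
        t = ramp_trace(rise_s=0.15)
        with pytest.raises(ValueError):
            fr.rtd(t, windows=((0, 200),))

    def test_least_squares_matches_endpoint_on_line(self):
        t = ramp_trace(slope=120.0)
        end = fr.rtd(t, method="endpoint")
        ls = fr.rtd(t, method="leastsq")
        assert ls == pytest.approx(end, rel=1e-4)


class TestMuscleQualityRatios:
    def test_muscle_quality(self):
        assert fr.muscle_quality([80, 40], 4.0) == 30.0
        assert fr.muscle_quality([90], 3.0) == 30.0
        with pytest.raises(ValueError):
            fr.muscle_quality([80], 0.0)

    def test_strength_ratio(self):
        assert fr.strength_ratio(0.6, 1.2) == 0.5
        assert fr.strength_ratio(0.7, 0.7) == 1.0
        with pytest.raises(ValueError):
            fr.strength_ratio(0.5, 0.0)
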