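import numpy as np
import pytest

from bhcvr import make_paradigm
from bhcvr.physio import (
    CapnoTrace,
    PetCO2Trace,
    compute_delta_petco2,
    correct_tube_delay,
    detect_end_tidal_peaks,
    interpolate_and_detrend,
)


class TestTubeDelay:
    def test_zero_delay_is_identity(self):
        trace = CapnoTrace(time=np.arange(5.0), co2=np.arange(5.0) + 30)
        out = correct_tube_delay(trace, 0.0)
        assert np.array_equal(out.time, trace.time)
        assert np.array_equal(out.co2, trace.co2)

    def test_shift_and_crop(self):
        trace = CapnoTrace(time=np.array([0.0, 1, 2, 3]), co2=np.array([10.0, 20, 30, 40]))
        out = correct_tube_delay(trace, 2.0)
        assert np.array_equal(out.time, [0.0, 1.0])
        assert np.array_equal(out.co2, [30.0, 40.0])

    def test_interior_round_trip(self):
        trace = CapnoTrace(time=np.arange(10.0), co2=np.linspace(30, 40, 10))
        shifted = correct_tube_delay(trace, 2.0)
        back = CapnoTrace(time=shifted.time + 2.0, co2=shifted.co2)
        assert np.array_equal(back.time, trace.time[2:])
        assert np.array_equal(back.co2, trace.co2[2:])

    def test_negative_delay_rejected(self):
        trace = CapnoTrace(time=np.arange(5.0), co2=np.full(5, 38.0))
        with pytest.raises(ValueError):
            correct_tube_delay(trace, -1.0)


class TestPeakDetection:
    def test_sinusoid_peak_count(self):
        t = np.arange(0, 60, 0.05)
        trace = CapnoTrace(time=t, co2=38 + 5 * np.sin(2 * np.pi * 0.25 * t))
        times, values = detect_end_tidal_peaks(trace, min_period=2.0)
        assert times.size == 15
        assert np.allclose(values, 43.0, atol=1e-3)

    def test_constant_trace_has_no_peaks(self):
        trace = CapnoTrace(time=np.arange(100.0), co2=np.full(100, 38.0))
        times, values = detect_end_tidal_peaks(trace)
        assert times.size == 0 and values.size == 0

    def test_recovers_simulated_end_tidal_values(self, noiseless_capno):
        times, values = detect_end_tidal_peaks(noiseless_capno.trace)
        assert times.size == noiseless_capno.peak_times.size
        assert np.allclose(times, noiseless_capno.peak_times, atol=1e-9)
        assert np.allclose(values, noiseless_capno.peak_values, atol=1e-9)

    def test_min_period_thins_close_peaks(self):
        t = np.arange(0, 30, 0.05)
        trace = CapnoTrace(time=t, co2=38 + 5 * np.sin(2 * np.pi * 0.5 * t))
        times, _ = detect_end_tidal_peaks(trace, min_period=3.0)
        assert np.all(np.diff(np.sort(times)) >= 3.0)


class TestInterpolateAndDetrend:
    def test_linear_drift_removed(self):
        t = np.arange(0, 200, 3.0)
        v = 35 + 0.02 * t
        out = interpolate_and_detrend((t, v))
        drift_span = np.ptp(v)
        assert np.abs(out.values - v.mean()).max() < 0.05 * drift_span

    def test_passband_amplitude_preserved(self):
        # 0.03 Hz is above the 0.01 Hz cutoff: amplitude within 10%
        t = np.arange(0, 400, 2.0)
        v = 40 + 3 * np.sin(2 * np.pi * 0.03 * t)
        out = interpolate_and_detrend((t, v), cutoff=100.0)
        z = out.values - out.values.mean()
        ref = 3 * np.sin(2 * np.pi * 0.03 * out.times)
        assert z.std() / ref.std() == pytest.approx(1.0, abs=0.1)

    def test_mean_preserving(self, noiseless_capno):
        times, values = detect_end_tidal_peaks(noiseless_capno.trace)
        out = interpolate_and_detrend((times, values))
        from scipy.interpolate import PchipInterpolator

        interp = PchipInterpolator(times, values)(out.times)
        assert out.values.mean() == pytest.approx(interp.mean(), abs=1e-9)

    def test_cubic_and_linear_interpolation_agree(self, noiseless_capno):
        times, values = detect_end_tidal_peaks(noiseless_capno.trace)
        from scipy.interpolate import PchipInterpolator

        out = interpolate_and_detrend((times, values))
        cubic = PchipInterpolator(times, values)(out.times)
        linear = np.interp(out.times, times, values)
        r = np.corrcoef(cubic, linear)[0, 1]
        assert r >= 0.99

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            interpolate_and_detrend((np.array([1.0]), np.array([38.0])))


def _trace_from_peaks(times, values):
    """PetCO2Trace stub carrying only the peak list (what ΔPetCO2 uses)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    return PetCO2Trace(
        grid_dt=0.1,
        t0=float(times[0]),
        values=np.interp(
            times[0] + 0.1 * np.arange(int((times[-1] - times[0]) / 0.1) + 1),
            times,
            values,
        ),
        peak_times=times,
        peak_values=values,
    )


class TestDeltaPetCO2:
    def _hand_built(self, post_values):
        # default layout: holds [89,104), [134,149), [179,194), [224,239)
        paradigm = make_paradigm()
        times, values = [], []
        for onset, end in paradigm.hold_intervals():
            for t in np.arange(onset - 6, onset, 2.0):  # late-baseline breaths
                times.append(t)
                values.append(38.0)
        for (onset, end), v in zip(paradigm.hold_intervals(), post_values):
            times.append(end + 3.0)
            values.append(v)
        order = np.argsort(times)
        trace = _trace_from_peaks(np.asarray(times)[order], np.asarray(values)[order])
        return trace, paradigm

    def test_hand_arithmetic(self):
        trace, paradigm = self._hand_built([46.0, 45.0, 47.0, 46.0])
        delta = compute_delta_petco2(trace, paradigm)
        assert np.allclose(delta.per_trial, [8.0, 7.0, 9.0, 8.0])
        assert delta.mean == pytest.approx(8.0)

    def test_four_trials_give_four_entries(self, petco2_trace, ist_paradigm):
        delta = compute_delta_petco2(petco2_trace, ist_paradigm)
        assert delta.per_trial.size == 4

    def test_constant_trace_gives_zero(self, ist_paradigm):
        times = np.arange(0.0, 269.0, 4.0)
        trace = _trace_from_peaks(times, np.full(times.size, 38.0))
        delta = compute_delta_petco2(trace, ist_paradigm)
        assert np.allclose(delta.per_trial, 0.0)

    def test_invariant_to_constant_offset(self, petco2_trace, ist_paradigm):
        base = compute_delta_petco2(petco2_trace, ist_paradigm)
        shifted = PetCO2Trace(
            grid_dt=petco2_trace.grid_dt,
            t0=petco2_trace.t0,
            values=petco2_trace.values + 5.0,
            peak_times=petco2_trace.peak_times,
            peak_values=petco2_trace.peak_values + 5.0,
        )
        out = compute_delta_petco2(shifted, ist_paradigm)
        assert np.allclose(out.per_trial, base.per_trial, atol=1e-12)

    def test_recovery_breaths_do_not_contaminate_baseline(self, ist_paradigm):
        # Simulated trace has elevated recovery breaths after each hold;
        # the baseline exclusion keeps per-trial deltas at the true value.
        from bhcvr.simulate import simulate_capnograph

        cap = simulate_capnograph(ist_paradigm, delta=8.0, noise_sd=0.0)
        trace = _trace_from_peaks(cap.peak_times, cap.peak_values)
        delta = compute_delta_petco2(trace, ist_paradigm)
        assert np.allclose(delta.per_trial, 8.0, atol=1e-12)

    def test_missing_post_hold_peak_is_nan_and_excluded(self):
        trace, paradigm = self._hand_built([46.0, 45.0, 47.0, 46.0])
        keep = trace.peak_times != paradigm.hold_intervals()[1][1] + 3.0
        trimmed = _trace_from_peaks(trace.peak_times[keep], trace.peak_values[keep])
        with pytest.warns(UserWarning, match="hold 1"):
            delta = compute_delta_petco2(trimmed, paradigm)
        assert np.isnan(delta.per_trial[1])
        assert delta.mean == pytest.approx(np.nanmean([8.0, np.nan, 9.0, 8.0]))
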