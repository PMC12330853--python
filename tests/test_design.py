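import numpy as np
import pytest

from bhcvr import make_paradigm
from bhcvr.dataset import BoldDataset
from bhcvr.design import (
    MODEL_GRID,
    GridSeries,
    build_block,
    build_confounds,
    build_petco2,
    convolve,
    detect_motion_outliers,
    extend_motion_params,
    shift_and_sample,
)
from bhcvr.hrf import make_params, sample_kernel


class TestBuildBlock:
    def test_boxcar_integral_matches_total_hold_time(self, ist_paradigm):
        series = build_block(ist_paradigm, 0.1)
        assert series.values.sum() * series.dt == pytest.approx(60.0, abs=0.2)

    def test_values_inside_and_outside_hold(self):
        p = make_paradigm(n_trials=1, hold=15, baseline=10, lead_in=0)
        series = build_block(p, 0.1)
        assert series.at(np.array([12.0]))[0] == 1.0
        assert series.at(np.array([5.0]))[0] == 0.0

    def test_padding_is_zero(self, ist_paradigm):
        series = build_block(ist_paradigm, 0.1, pad=24.0)
        assert series.t0 == -24.0
        assert series.at(np.array([-20.0, ist_paradigm.total_duration + 20])).sum() == 0


class TestBuildPetCO2:
    def test_constant_trace_gives_constant_source(self, ist_paradigm):
        class Stub:
            times = np.arange(0.0, 270.0, 0.1)
            values = np.full(2700, 40.0)

        series = build_petco2(Stub(), 0.1, total_duration=269.0)
        assert np.allclose(series.values, 40.0)

    def test_grid_aligned_trace_is_identity_on_overlap(self, petco2_trace):
        series = build_petco2(petco2_trace, 0.1, total_duration=269.0)
        t = petco2_trace.times[(petco2_trace.times > 5) & (petco2_trace.times < 260)]
        assert np.allclose(series.at(t), np.interp(t, petco2_trace.times, petco2_trace.values), atol=1e-9)

    def test_correlates_with_generator_truth(self, noiseless_capno, petco2_trace):
        # compare against the generator's ideal course passed through the
        # same 100 s high-pass the processed trace went through
        from scipy.signal import butter, sosfiltfilt

        series = build_petco2(petco2_trace, 0.1, total_duration=269.0)
        ideal = noiseless_capno.ideal_petco2()
        sos = butter(2, (1 / 100.0) / (0.5 / ideal.dt), "highpass", output="sos")
        ideal_hp = sosfiltfilt(sos, ideal.values)
        t = np.arange(5.0, 264.0, 0.5)
        r = np.corrcoef(
            series.at(t), np.interp(t, ideal.times, ideal_hp)
        )[0, 1]
        assert r >= 0.95

    def test_short_coverage_rejected(self):
        class Stub:
            times = np.arange(0.0, 100.0, 0.1)
            values = np.sin(np.arange(0.0, 100.0, 0.1)) + 40

        with pytest.raises(ValueError, match="cover"):
            build_petco2(Stub(), 0.1, total_duration=269.0)


class TestConvolve:
    def test_none_kernel_is_identity(self, ist_paradigm):
        series = build_block(ist_paradigm, 0.1)
        assert convolve(series, None) is series

    def test_impulse_reproduces_kernel(self):
        kernel = sample_kernel(make_params(6, "single"))
        values = np.zeros(600)
        values[0] = 1.0
        out = convolve(GridSeries(t0=0.0, dt=0.1, values=values), kernel)
        assert np.allclose(out.values[: kernel.samples.size], kernel.samples)

    def test_unit_sum_kernel_preserves_plateau(self):
        kernel = sample_kernel(make_params(6, "single"))
        values = np.zeros(3000)
        values[500:2500] = 1.0  # 200 s hold >> kernel support
        out = convolve(GridSeries(t0=0.0, dt=0.1, values=values), kernel)
        assert out.values[1500] == pytest.approx(1.0, abs=1e-6)

    def test_linearity(self, rng):
        kernel = sample_kernel(make_params(5, "double"))
        x = rng.standard_normal(800)
        y = rng.standard_normal(800)
        gs = lambda v: GridSeries(t0=0.0, dt=0.1, values=v)
        lhs = convolve(gs(2.0 * x + 3.0 * y), kernel).values
        rhs = 2.0 * convolve(gs(x), kernel).values + 3.0 * convolve(gs(y), kernel).values
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_dt_mismatch_rejected(self):
        kernel = sample_kernel(make_params(6, "single"), dt=0.2)
        with pytest.raises(ValueError, match="dt"):
            convolve(GridSeries(t0=0.0, dt=0.1, values=np.ones(100)), kernel)


class TestShiftAndSample:
    @pytest.fixture()
    def source(self, ist_paradigm):
        kernel = sample_kernel(make_params(6, "single"))
        return convolve(build_block(ist_paradigm, 0.1), kernel)

    def test_zero_lag_is_plain_downsampling(self, source):
        out = shift_and_sample(source, 0.0, 1.26, 213, normalize=False)
        assert np.allclose(out, source.at(np.arange(213) * 1.26))

    def test_shift_round_trip(self, source):
        fwd = shift_and_sample(source, 3.0, 1.26, 213, normalize=False)
        # delaying by +3 then sampling equals sampling the source at t-3
        assert np.allclose(fwd, source.at(np.arange(213) * 1.26 - 3.0), atol=1e-9)
        back = shift_and_sample(source, -3.0, 1.26, 213, normalize=False)
        t = np.arange(213) * 1.26
        assert np.allclose(back, source.at(t + 3.0), atol=1e-9)

    def test_normalization_contract(self, source):
        out = shift_and_sample(source, 2.0, 1.26, 213)
        assert out.min() == 0.0
        assert out.max() == 1.0

    def test_normalization_idempotent(self, source):
        out = shift_and_sample(source, 2.0, 1.26, 213)
        lo, hi = out.min(), out.max()
        again = (out - lo) / (hi - lo)
        assert np.array_equal(out, again)

    def test_lag_beyond_padding_rejected(self, source):
        with pytest.raises(ValueError, match="padding"):
            shift_and_sample(source, 30.0, 1.26, 213)

    def test_constant_series_rejected(self):
        series = GridSeries(t0=-24.0, dt=0.1, values=np.full(3000, 5.0))
        with pytest.raises(ValueError, match="degenerate"):
            shift_and_sample(series, 0.0, 1.26, 100)


class TestSixModels:
    def test_model_grid_enumerates_six_distinct_families(self):
        assert len(MODEL_GRID) == 6
        assert len(set(MODEL_GRID)) == 6
        assert {rt for rt, _ in MODEL_GRID} == {"PetCO2", "Block"}
        assert {c for _, c in MODEL_GRID} == {"WoC", "CSg", "CDb"}


class TestExtendMotionParams:
    def test_zero_motion_gives_24_zero_columns(self):
        out, names = extend_motion_params(np.zeros((50, 6)))
        assert out.shape == (50, 24)
        assert len(names) == 24
        assert not out.any()

    def test_constant_motion(self):
        m = np.full((30, 6), 2.0)
        out, _ = extend_motion_params(m)
        assert np.allclose(out[:, :6], 2.0)
        assert np.allclose(out[1:, 6:12], 0.0)  # derivatives
        assert np.allclose(out[:, 12:18], 4.0)  # squares
        assert np.allclose(out[:, 18:], 0.0)  # squared derivatives

    def test_backward_difference_first_row_zero(self, rng):
        m = rng.standard_normal((40, 6))
        out, _ = extend_motion_params(m)
        assert np.allclose(out[0, 6:12], 0.0)
        assert np.allclose(out[1:, 6:12], np.diff(m, axis=0))

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError):
            extend_motion_params(np.zeros((10, 5)))


def _toy_bold(data):
    shape = data.shape[:3]
    mask = np.ones(shape, dtype=bool)
    return BoldDataset(
        data=data, tr=1.0, brain_mask=mask, gm_mask=mask, wm_mask=mask
    )


class TestMotionOutliers:
    def test_identical_volumes_give_no_outliers(self):
        data = np.tile(np.full((4, 4, 2, 1), 100.0), (1, 1, 1, 20))
        spikes, indices, metric = detect_motion_outliers(_toy_bold(data))
        assert indices.size == 0
        assert spikes.shape == (20, 0)

    def test_single_perturbed_volume_flagged_exactly(self):
        data = np.tile(np.full((4, 4, 2, 1), 100.0), (1, 1, 1, 20))
        data[..., 7] += 5.0
        spikes, indices, metric = detect_motion_outliers(_toy_bold(data))
        assert list(indices) == [7]
        assert spikes[:, 0].sum() == 1.0 and spikes[7, 0] == 1.0

    def test_reference_volume_metric_is_zero(self, rng):
        data = 100 + rng.standard_normal((4, 4, 2, 21))
        _, _, metric = detect_motion_outliers(_toy_bold(data))
        assert metric[21 // 2] == 0.0

    def test_confound_matrix_width(self, rng):
        data = np.tile(np.full((4, 4, 2, 1), 100.0), (1, 1, 1, 20))
        data[..., 3] += 5.0
        bold = _toy_bold(data)
        bold.motion6 = rng.standard_normal((20, 6))
        conf = build_confounds(bold)
        assert conf.columns.shape[1] == 24 + 1
        spike = conf.columns[:, -1]
        assert spike.sum() == 1.0 and spike[3] == 1.0
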