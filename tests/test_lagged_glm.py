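import numpy as np
import pytest

from bhcvr import make_paradigm
from bhcvr.dataset import BoldDataset
from bhcvr.design import (
    ConfoundMatrix,
    GridSeries,
    build_block,
    convolve,
    shift_and_sample,
)
from bhcvr.hrf import make_params, sample_kernel
from bhcvr.lagged_glm import (
    estimate_bulk_lag,
    fit_voxel_glm,
    make_lag_grid,
    optimize_delay_and_lag,
    sweep_and_select,
)

TR = 1.26
N_VOLS = 213


@pytest.fixture(scope="module")
def source():
    paradigm = make_paradigm()
    kernel = sample_kernel(make_params(6, "single"))
    return convolve(build_block(paradigm, 0.1), kernel)


def _column(source, lag, normalize=True):
    return shift_and_sample(source, lag, TR, N_VOLS, normalize=normalize)


def _bold_from_rows(rows, tr=TR):
    rows = np.asarray(rows, dtype=float)
    v = rows.shape[0]
    mask = np.ones((v, 1, 1), dtype=bool)
    return BoldDataset(
        data=rows.reshape(v, 1, 1, -1),
        tr=tr,
        brain_mask=mask,
        gm_mask=mask,
        wm_mask=mask,
    )


def _brute_force(y, columns, grid, confounds):
    """Independent per-lag OLS loop (lstsq on the explicit design)."""
    n = y.size
    c = confounds.columns if confounds is not None else np.empty((n, 0))
    best = (-np.inf, None, None)
    for i, lag in enumerate(grid.absolute_lags):
        x_full = np.column_stack([columns[i], c, np.ones(n)])
        b, *_ = np.linalg.lstsq(x_full, y, rcond=None)
        rss_full = ((y - x_full @ b) ** 2).sum()
        x_red = np.column_stack([c, np.ones(n)])
        br, *_ = np.linalg.lstsq(x_red, y, rcond=None)
        rss_red = ((y - x_red @ br) ** 2).sum()
        f = (rss_red - rss_full) / (rss_full / (n - x_full.shape[1]))
        if f > best[0]:
            best = (f, b[0], lag)
    return best  # (F, beta, lag)


class TestBulkLag:
    def test_regressor_against_itself_gives_zero(self, source):
        y = _column(source, 0.0, normalize=False)
        assert estimate_bulk_lag(y, source, TR) == 0.0

    def test_recovers_known_delay(self, source):
        y = _column(source, 5.0, normalize=False)
        assert estimate_bulk_lag(y, source, TR) == 5.0

    def test_boundary_hit_warns_and_clamps(self, source):
        # build a series delayed far beyond the search range
        y = source.at(np.arange(N_VOLS) * TR - 20.0)
        with pytest.warns(UserWarning, match="boundary"):
            lag = estimate_bulk_lag(y, source, TR, search=15.0)
        assert lag == 15.0

    def test_constant_series_rejected(self, source):
        with pytest.raises(ValueError):
            estimate_bulk_lag(np.full(N_VOLS, 3.0), source, TR)


class TestFitVoxelGLM:
    def test_exact_linear_relation(self, source):
        x = _column(source, 0.0)
        beta, f = fit_voxel_glm(2.0 * x + 3.0, x)
        assert beta == pytest.approx(2.0, abs=1e-10)
        assert f > 1e10  # residuals are zero

    def test_partial_f_closed_form(self, source, rng):
        # with only an intercept, F = r^2 (T-2) / (1 - r^2)
        x = _column(source, 0.0)
        y = 1.5 * x + rng.standard_normal(N_VOLS)
        beta, f = fit_voxel_glm(y, x)
        r = np.corrcoef(x, y)[0, 1]
        expected = r**2 * (N_VOLS - 2) / (1 - r**2)
        assert f == pytest.approx(expected, abs=1e-9 * expected)

    def test_orthogonal_confound_leaves_beta(self, source, rng):
        x = _column(source, 0.0)
        y = 1.5 * x + rng.standard_normal(N_VOLS)
        # build a confound orthogonal to 1, x and y
        c = rng.standard_normal(N_VOLS)
        basis = np.linalg.qr(np.column_stack([np.ones(N_VOLS), x, y]))[0]
        c -= basis @ (basis.T @ c)
        beta0, _ = fit_voxel_glm(y, x)
        beta1, _ = fit_voxel_glm(y, x, ConfoundMatrix(columns=c[:, None], names=("c",)))
        assert beta1 == pytest.approx(beta0, abs=1e-9)

    def test_insufficient_dof_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_voxel_glm(np.arange(3.0), np.array([0.0, 1.0, 0.5]),
                          ConfoundMatrix(columns=np.eye(3), names=("a", "b", "c")))


@pytest.fixture(scope="module")
def grid():
    return make_lag_grid(0.0)


@pytest.fixture(scope="module")
def columns(source, grid):
    return np.stack([_column(source, lag) for lag in grid.absolute_lags])


class TestSweepAndSelect:
    def test_noiseless_voxels_recover_lag_and_amplitude(self, source, grid, columns):
        true_lags = [-3.0, 0.0, 4.0, 7.0]
        amp = 5.0
        rows = [1000.0 + amp * _column(source, lag) for lag in true_lags]
        res = sweep_and_select(_bold_from_rows(rows), columns, grid)
        sel = res.lag_opt.reshape(-1)
        assert np.array_equal(sel, true_lags)
        assert np.allclose(res.beta.reshape(-1), amp, rtol=1e-6)

    def test_matches_brute_force_on_50_voxels(self, source, grid, columns, rng):
        y = rng.standard_normal((50, N_VOLS)) * 2 + 100
        conf = ConfoundMatrix(
            columns=rng.standard_normal((N_VOLS, 4)), names=tuple("abcd")
        )
        res = sweep_and_select(_bold_from_rows(y), columns, grid, conf)
        for v in range(50):
            f_bf, beta_bf, lag_bf = _brute_force(y[v], columns, grid, conf)
            assert abs(res.beta.reshape(-1)[v] - beta_bf) < 1e-8
            assert res.lag_opt.reshape(-1)[v] == lag_bf

    def test_argmax_contract(self, source, grid, columns, rng):
        from bhcvr.lagged_glm import _nuisance_basis, _sweep_core

        y = rng.standard_normal((30, N_VOLS)) + 100
        q, _ = _nuisance_basis(N_VOLS, None)
        beta, f, _ = _sweep_core(y, columns, q)
        res = sweep_and_select(_bold_from_rows(y), columns, grid)
        sel_f = res.partial_f.reshape(-1)
        assert np.all(sel_f[None, :] >= f - 1e-10)

    def test_scaling_invariance(self, source, grid, columns, rng):
        y = rng.standard_normal((10, N_VOLS)) + 50
        a = sweep_and_select(_bold_from_rows(y), columns, grid)
        b = sweep_and_select(_bold_from_rows(7.0 * y), columns, grid)
        assert np.allclose(b.beta, 7.0 * a.beta, rtol=1e-9)
        assert np.allclose(b.partial_f, a.partial_f, rtol=1e-9)
        assert np.array_equal(a.lag_opt, b.lag_opt)

    def test_pure_noise_voxel_no_crash(self, grid, columns, rng):
        y = rng.standard_normal((5, N_VOLS))
        res = sweep_and_select(_bold_from_rows(y), columns, grid)
        assert np.all(np.isfinite(res.partial_f))
        assert np.all(np.isin(res.lag_opt.reshape(-1), grid.absolute_lags))

    def test_exact_ties_prefer_smallest_offset_then_negative(self, grid):
        # duplicate the same column everywhere: every lag ties exactly
        col = np.sin(np.arange(N_VOLS) / 10.0)
        col = (col - col.min()) / np.ptp(col)
        columns = np.tile(col, (grid.absolute_lags.size, 1))
        y = 10.0 + 2.0 * col
        res = sweep_and_select(_bold_from_rows([y]), columns, grid)
        assert res.lag_opt.reshape(-1)[0] == 0.0  # smallest |offset|
        # remove the 0-offset candidate's uniqueness: make offsets ±1 tie
        from bhcvr.lagged_glm import LagGrid

        keep = grid.offsets != 0
        res2 = sweep_and_select(
            _bold_from_rows([y]),
            columns[keep],
            LagGrid(
                bulk_lag=0.0,
                offsets=grid.offsets[keep],
                absolute_lags=grid.absolute_lags[keep],
            ),
        )
        assert res2.lag_opt.reshape(-1)[0] == -1.0  # more negative wins

    def test_prewhitening_recovers_amplitude_on_ar1_noise(self, source, grid, columns, rng):
        x = _column(source, 0.0)
        n = N_VOLS
        eps = np.zeros(n)
        white = rng.standard_normal(n)
        for t in range(1, n):
            eps[t] = 0.5 * eps[t - 1] + white[t]
        y = 100 + 4.0 * x + eps
        res = sweep_and_select(
            _bold_from_rows([y]), columns, grid, prewhiten=True
        )
        assert res.beta.reshape(-1)[0] == pytest.approx(4.0, abs=1.0)


class TestJointDelaySearch:
    def test_noiseless_delay_recovery(self):
        paradigm = make_paradigm()
        grid = make_lag_grid(0.0)
        banks = {}
        sources = {}
        for d in (3.0, 6.0, 9.0):
            src = convolve(
                build_block(paradigm, 0.1), sample_kernel(make_params(d, "single"))
            )
            sources[d] = src
            banks[d] = np.stack(
                [_column(src, lag) for lag in grid.absolute_lags]
            )
        rows = [200.0 + 3.0 * _column(sources[6.0], 2.0) for _ in range(4)]
        res = optimize_delay_and_lag(_bold_from_rows(rows), banks, grid)
        assert np.all(res.delay_opt.reshape(-1) == 6.0)
        assert np.all(res.lag_opt.reshape(-1) == 2.0)

    def test_matches_brute_force_joint_loop(self, rng):
        paradigm = make_paradigm()
        grid = make_lag_grid(0.0)
        banks = {}
        for d in (3.0, 6.0, 9.0):
            src = convolve(
                build_block(paradigm, 0.1), sample_kernel(make_params(d, "single"))
            )
            banks[d] = np.stack([_column(src, lag) for lag in grid.absolute_lags])
        y = rng.standard_normal((20, N_VOLS)) + 100
        res = optimize_delay_and_lag(_bold_from_rows(y), banks, grid)
        for v in range(20):
            best = (-np.inf, None, None)
            for d in (3.0, 6.0, 9.0):
                f_bf, beta_bf, lag_bf = _brute_force(y[v], banks[d], grid, None)
                if f_bf > best[0]:
                    best = (f_bf, d, lag_bf)
            assert res.delay_opt.reshape(-1)[v] == best[1]
            assert res.lag_opt.reshape(-1)[v] == best[2]

    def test_requires_two_delays(self, rng):
        grid = make_lag_grid(0.0)
        with pytest.raises(ValueError):
            optimize_delay_and_lag(
                _bold_from_rows(rng.standard_normal((2, N_VOLS))),
                {6.0: np.zeros((19, N_VOLS))},
                grid,
            )
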