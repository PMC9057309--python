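"""DeltaMSE-RSFC: sweeps, bias extrapolation, and optimization."""

import numpy as np
import pytest

from mbcensor.mse_rsfc import (
    BiasEstimate,
    ResampledSweep,
    delta_mse,
    estimate_uncensored_bias,
    group_mse_to_truth,
    optimize_censoring,
    optimize_single,
    optimize_2d_grid,
    resample_sweep,
    sweep_censoring,
)


def make_resampled(percents, delta_bias, var_c=None, n_s=None, var_u=None, n_su=10):
    P, K = delta_bias.shape
    return ResampledSweep(
        percents=percents,
        delta_bias=delta_bias,
        var_c=var_c if var_c is not None else np.zeros((P, K)),
        n_s=n_s if n_s is not None else np.full(P, float(n_su)),
        n_su=n_su,
        var_u=var_u if var_u is not None else np.zeros(K),
        grid_percents=percents,
        grid_params=percents,
        method="synthetic",
    )


class TestBiasAlgebra:
    def test_hand_case(self):
        # Bias_u = 0.05, DeltaBias = -0.02:
        # change in squared bias = 0.03^2 - 0.05^2 = -0.0016; Bias_c^2 = 0.0009
        p = np.array([0.0, 10.0])
        res = make_resampled(p, np.array([[0.0], [-0.02]]), n_su=1)
        bias = BiasEstimate(bias_u=np.array([0.05]), slope=np.array([0.0005]))
        curve, neg = delta_mse(res, bias)
        # with zero variance and N=1, DeltaMSE = Bias_c^2 - Bias_u^2
        assert curve[-1] == pytest.approx(-0.0016, abs=1e-15)
        assert (0.05 - 0.02) ** 2 == pytest.approx(0.0009)
        assert neg == 0

    def test_full_bias_removal_collapses(self):
        p = np.array([0.0, 10.0])
        res = make_resampled(p, np.array([[0.0], [-0.05]]), n_su=1)
        bias = BiasEstimate(bias_u=np.array([0.05]), slope=np.array([0.0005]))
        curve, _ = delta_mse(res, bias)
        assert curve[-1] == pytest.approx(-0.05**2, abs=1e-15)

    def test_zero_censoring_point_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        K = 7
        p = np.linspace(0, 40, 9)
        db = -0.001 * p[:, None] * rng.uniform(0.5, 2.0, K)
        db[0] = 0.0
        var = rng.uniform(0.01, 0.02, (9, K))
        var[0] = 0.015
        res = make_resampled(p, db, var_c=var, var_u=var[0], n_su=20, n_s=np.full(9, 20.0))
        bias = estimate_uncensored_bias(res)
        curve, _ = delta_mse(res, bias)
        assert curve[0] == 0.0


class TestBiasExtrapolation:
    def test_noiseless_line_exact(self):
        p = np.arange(0, 80.01, 0.01)
        db = -0.001 * p[:, None]
        res = make_resampled(p, db)
        est = estimate_uncensored_bias(res)
        assert est.bias_u[0] == pytest.approx(0.1, abs=1e-10)

    def test_all_zero_curve(self):
        p = np.arange(0, 80.01, 0.01)
        res = make_resampled(p, np.zeros((p.size, 3)))
        est = estimate_uncensored_bias(res)
        assert np.all(est.bias_u == 0)

    def test_robust_to_gross_outliers(self):
        rng = np.random.default_rng(1)
        p = np.arange(0, 80.01, 0.01)
        y = 0.001 * p + rng.normal(0, 1e-5, p.size)
        bad = p > 76  # 5% gross contamination at high removal
        y[bad] += rng.uniform(0.1, 0.2, bad.sum())  # one-sided instability near 100%
        res = make_resampled(p, -y[:, None])
        est = estimate_uncensored_bias(res)
        ols = (y @ p) / (p @ p) * 100
        assert abs(est.bias_u[0] - 0.1) < 0.05 * 0.1
        assert abs(ols - 0.1) > 0.15 * 0.1


class TestOptimizeSingle:
    def test_parabola_minimum(self):
        p = np.arange(0, 80.01, 0.01)
        curve = (p - 35.0) ** 2
        res = optimize_single(p, curve)
        assert res.percent_opt == pytest.approx(35.0, abs=0.01)

    def test_monotone_curve_boundary(self):
        p = np.arange(0, 80.01, 0.01)
        res = optimize_single(p, 1e-4 * p)
        assert res.percent_opt == 0.0

    def test_search_range_respected(self):
        p = np.arange(0, 100.01, 0.01)
        curve = -(p - 95.0) ** 2  # global min at the edges; range caps at 80
        res = optimize_single(p, curve, search_range=(0, 80))
        assert res.percent_opt == 0.0

    def test_nonfinite_curve_rejected(self):
        p = np.arange(0, 10.01, 0.01)
        curve = np.zeros_like(p)
        curve[500] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            optimize_single(p, curve, search_range=(0, 10))

    def test_inverse_parameter_interpolation(self):
        p = np.arange(0, 80.01, 0.01)
        curve = (p - 20.0) ** 2
        grid_p = np.array([0.0, 10.0, 30.0, 60.0])
        grid_param = np.array([np.inf, 0.5, 0.3, 0.1])
        res = optimize_single(p, curve, percent_to_param=(grid_p, grid_param))
        assert res.percent_opt == pytest.approx(20.0, abs=0.01)
        assert res.param_opt == pytest.approx(0.4, abs=0.001)


class TestSweep:
    def test_quantile_targets_realized(self, small_dataset):
        sweep = sweep_censoring(
            small_dataset, method="lpf-fd", percent_targets=np.array([0.0, 10.0, 20.0]),
            seed=0, min_vol=100,
        )
        assert sweep.percents[0] == 0.0
        assert sweep.percents[1] == pytest.approx(10.0, abs=1.0)
        assert sweep.percents[2] == pytest.approx(20.0, abs=1.0)

    def test_anchor_point_values(self, small_dataset):
        sweep = sweep_censoring(
            small_dataset, method="lpf-fd", percent_targets=np.array([0.0, 15.0]),
            seed=0, min_vol=100,
        )
        assert np.all(sweep.delta_bias[0] == 0)
        assert np.all(sweep.delta_bias <= 0)
        assert sweep.n_s[0] == sweep.n_su
        assert np.allclose(sweep.var_u, sweep.var_c[0])

    def test_gev_dv_percent_monotone_in_dg(self, small_dataset):
        sweep = sweep_censoring(
            small_dataset, method="gev-dv",
            percent_targets=np.array([0.0, 10.0, 25.0, 40.0]), seed=0, min_vol=100,
        )
        assert np.all(np.diff(sweep.percents) > 0)

    def test_combined_ratio_union_property(self, small_dataset):
        from mbcensor.censoring import apply_exclusion, fit_gev, gev_dv_threshold, mask_from_threshold
        from mbcensor.framewise import compute_dv, compute_fd

        ratio = 0.05
        sweep = sweep_censoring(
            small_dataset, method="combined-ratio", ratio=ratio,
            percent_targets=np.array([0.0, 20.0]), seed=0, min_vol=100,
        )
        phi = sweep.grid_params[1]
        # combined mask censors at least what either single criterion censors
        for key, sim in small_dataset.runs.items():
            fd = compute_fd(sim.motion, "lpf").values
            dv = compute_dv(sim.ts.roi_data, sim.ts.tr, "lpf").values
            fit = fit_gev(dv)
            thr = gev_dv_threshold(fit, phi / ratio, values=dv[1:])
            fd_censored = fd > phi
            dv_censored = dv > thr if np.isfinite(thr) else np.zeros_like(fd_censored)
            combined_rate = (fd_censored | dv_censored).mean()
            assert combined_rate >= fd_censored.mean()
            assert combined_rate >= dv_censored.mean()
            break  # one run suffices; loop kept for clarity

    def test_resampling_hits_fine_grid(self, small_dataset):
        sweep = sweep_censoring(
            small_dataset, method="lpf-fd",
            percent_targets=np.array([0.0, 10.0, 20.0, 30.0]), seed=0, min_vol=100,
        )
        res = resample_sweep(sweep)
        assert res.percents[1] - res.percents[0] == pytest.approx(0.01)
        assert res.percents[0] == 0.0


class TestTruthReferencedMSE:
    def test_bias_variance_identity(self):
        # mean_i (z_i - theta)^2 == var(ddof=0) + (mean - theta)^2, exactly
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((50, 20))
        theta = rng.standard_normal(20)
        brute = np.mean((Z - theta) ** 2, axis=0)
        decomp = Z.var(axis=0, ddof=0) + (Z.mean(axis=0) - theta) ** 2
        assert np.allclose(brute, decomp, atol=1e-12)

    def test_group_mse_decreases_with_n(self):
        rng = np.random.default_rng(3)
        truth = np.zeros(10)
        Z = rng.standard_normal((80, 10)) * 0.1
        assert group_mse_to_truth(Z, truth) < group_mse_to_truth(Z[:10], truth) * 2


class TestEndToEndOptimization:
    def test_censoring_beats_uncensored_on_contaminated_data(self, small_dataset):
        res = optimize_censoring(
            small_dataset, method="lpf-fd",
            percent_targets=np.arange(0.0, 45.0, 5.0), seed=0, min_vol=100,
        )
        assert 0 <= res.percent_opt <= 80
        assert res.delta_mse_opt <= 0  # no worse than not censoring

    def test_2d_degenerate_grid(self, small_dataset):
        res = optimize_2d_grid(
            small_dataset, phi_grid=np.array([np.inf]), dg_grid=np.array([1e9]),
            seed=0, min_vol=100,
        )
        assert res.percent_opt == pytest.approx(0.0)
        assert res.extra["d_g_opt"] == 1e9
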