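"""Connectivity pipeline: normalization, nuisance, preprocessing,
partial correlations."""

import numpy as np
import pytest

from mbcensor.io_formats import MotionTrace, RunTimeseries
from mbcensor.rsfc import (
    build_mp_regressors,
    censored_z,
    censored_z_multi,
    compute_nuisance_signals,
    dataset_rsfc,
    make_run_context,
    mode1000_normalize,
    partial_corr_matrix,
    preprocess_run,
    subject_rsfc,
)
from mbcensor.synth import SynthConfig, simulate_dataset


class TestMode1000:
    def test_constant_field(self):
        scaled, scale = mode1000_normalize(np.full((10, 20), 250.0))
        assert np.allclose(scaled, 1000.0)
        assert scale == pytest.approx(4.0)

    def test_histogram_mode_consistency(self):
        x = np.random.default_rng(0).normal(500.0, 10.0, 1_000_000)
        _, scale = mode1000_normalize(x)
        assert 1000.0 / scale == pytest.approx(500.0, abs=2.0)

    def test_near_idempotent(self):
        x = np.random.default_rng(1).normal(800.0, 30.0, 200_000)
        once, _ = mode1000_normalize(x)
        twice, _ = mode1000_normalize(once)
        assert np.abs(twice / once - 1).max() < 0.005

    def test_nonpositive_mode_rejected(self):
        with pytest.raises(ValueError):
            mode1000_normalize(np.full(1000, -5.0))


class TestNuisanceSignals:
    def test_constant_image(self):
        data = np.full((6, 6, 6, 4), 3.0)
        mask = np.ones((6, 6, 6), bool)
        ns = compute_nuisance_signals(data, mask, mask, mask)
        assert np.allclose(ns.gs, 3.0) and np.allclose(ns.wm, 3.0) and np.allclose(ns.csf, 3.0)

    def test_cube_erosion_depth(self):
        # 5x5x5 solid cube, 6-connected erosion: 125 -> 27 -> 1 -> (empty),
        # so two iterations apply and one voxel remains
        data = np.zeros((9, 9, 9, 2))
        data[2, 2, 2] = [7.0, 8.0]  # value at the surviving center voxel... see mask below
        mask = np.zeros((9, 9, 9), bool)
        mask[:5, :5, :5] = True
        data[:] = 1.0
        data[2, 2, 2] = [7.0, 8.0]
        ns = compute_nuisance_signals(data, np.ones((9, 9, 9), bool), mask, mask)
        assert ns.erosion_iterations["wm"] == 2
        assert np.allclose(ns.wm, [7.0, 8.0])  # only the cube center survives

    def test_single_voxel_mask_never_eroded(self):
        data = np.ones((4, 4, 4, 3))
        single = np.zeros((4, 4, 4), bool)
        single[1, 1, 1] = True
        ns = compute_nuisance_signals(data, np.ones((4, 4, 4), bool), single, single)
        assert ns.erosion_iterations["wm"] == 0

    def test_empty_mask_rejected(self):
        data = np.ones((4, 4, 4, 3))
        with pytest.raises(ValueError):
            compute_nuisance_signals(
                data, np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool),
                np.ones((4, 4, 4), bool),
            )


class TestPreprocessRun:
    def test_constant_series_zeroed(self):
        run = RunTimeseries(np.full((3, 300), 5.0), tr=0.72)
        out = preprocess_run(run)
        assert np.allclose(out.roi_data, 0.0, atol=1e-8)
        assert out.filtered and out.trimmed

    def test_linear_ramp_removed_exactly(self):
        from mbcensor.rsfc import _fit_trend_on_kept

        ramp = np.outer([1.0, -2.0], np.arange(300.0)) + np.array([[3.0], [7.0]])
        detr = _fit_trend_on_kept(ramp, np.ones(300, bool))
        assert np.abs(detr).max() < 1e-10

    def test_censored_spike_does_not_propagate(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((4, 300))
        keep = np.ones(300, bool)
        keep[150] = False
        spiked = base.copy()
        spiked[:, 150] += 50.0
        out_spiked = preprocess_run(RunTimeseries(spiked, tr=0.72), keep)
        out_clean = preprocess_run(RunTimeseries(base, tr=0.72), keep)
        assert np.allclose(out_spiked.roi_data, out_clean.roi_data, atol=1e-10)

    def test_frame_accounting(self):
        keep = np.ones(300, bool)
        keep[100:110] = False  # censored inside the retained window
        out = preprocess_run(RunTimeseries(np.random.default_rng(1).standard_normal((2, 300)), tr=0.72), keep)
        assert out.roi_data.shape[1] == 300 - 60 - 10

    def test_too_few_kept_frames(self):
        keep = np.zeros(300, bool)
        keep[0] = True
        with pytest.raises(ValueError):
            preprocess_run(RunTimeseries(np.ones((2, 300)), tr=0.72), keep)


class TestPartialCorr:
    def test_intercept_only_equals_plain_correlation(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((3, 80))
        z = partial_corr_matrix(data, np.ones((80, 1)))
        plain = np.corrcoef(data)[np.triu_indices(3, 1)]
        assert np.allclose(np.tanh(z), plain, atol=1e-12)

    def test_annihilation(self):
        rng = np.random.default_rng(3)
        col = rng.standard_normal(60)
        data = np.vstack([col, rng.standard_normal(60)])
        design = np.column_stack([col, np.ones(60)])
        z = partial_corr_matrix(data, design)
        assert np.abs(z[0]) < 1e-10

    def test_brute_force_oracle(self):
        # independent oracle: explicit normal-equations residualization
        rng = np.random.default_rng(4)
        data = rng.standard_normal((5, 60))
        design = np.column_stack([rng.standard_normal((60, 5)), np.ones(60)])
        z = partial_corr_matrix(data, design)
        resid = []
        for row in data:
            beta = np.linalg.solve(design.T @ design, design.T @ row)
            resid.append(row - design @ beta)
        resid = np.asarray(resid)
        iu = np.triu_indices(5, 1)
        expected = np.arctanh(np.corrcoef(resid)[iu])
        assert np.allclose(z, expected, atol=1e-10)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((2, 100))
        design = np.column_stack([rng.standard_normal((100, 4)), np.ones(100)])
        q, _ = np.linalg.qr(design)
        resid = data.T - q @ (q.T @ data.T)
        assert np.abs(design.T @ resid).max() < 1e-10

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((3, 90))
        design = np.column_stack([rng.standard_normal((90, 2)), np.ones(90)])
        z0 = partial_corr_matrix(data, design)
        data2 = data * np.array([[2.0], [-0.5], [10.0]]) + np.array([[1.0], [0.0], [-4.0]])
        design2 = design * np.array([3.0, 0.1, 1.0])
        z1 = partial_corr_matrix(data2, design2)
        assert np.allclose(np.abs(z0), np.abs(z1), atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(7)
        col = rng.standard_normal(50)
        design = np.column_stack([col, col, np.ones(50)])
        with pytest.raises(ValueError, match="collinear"):
            partial_corr_matrix(rng.standard_normal((2, 50)), design)

    def test_too_few_frames(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="frames"):
            partial_corr_matrix(rng.standard_normal((2, 10)), rng.standard_normal((10, 9)))


class TestSubjectRSFC:
    def test_single_run_identity(self):
        z = np.array([0.1, 0.2])
        assert np.array_equal(subject_rsfc([z]), z)

    def test_two_run_mean_and_order_invariance(self):
        a, b = np.array([0.1, -0.3]), np.array([0.5, 0.1])
        assert np.allclose(subject_rsfc([a, b]), (a + b) / 2)
        assert np.allclose(subject_rsfc([a, b]), subject_rsfc([b, a]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            subject_rsfc([])


class TestDesignStructure:
    def test_mp_block_width_and_conventions(self):
        rng = np.random.default_rng(9)
        mp = MotionTrace(rng.normal(0, 0.05, (300, 6)), tr=0.72)
        block = build_mp_regressors(mp)
        assert block.shape == (300, 24)
        # derivative columns start at 0 by the backward-difference convention
        assert np.allclose(block[0, 12:18], 0.0)
        # squared columns are squares of the filtered MPs
        assert np.allclose(block[:, 6:12], block[:, :6] ** 2)

    def test_design_column_counts(self):
        rng = np.random.default_rng(10)
        T = 300
        nuis = {"WM": rng.standard_normal(T), "CSF": rng.standard_normal(T),
                "GS": rng.standard_normal(T)}
        run = RunTimeseries(rng.standard_normal((3, T)), tr=0.72, nuisance=nuis)
        mp = MotionTrace(rng.normal(0, 0.05, (T, 6)), tr=0.72)
        ctx = make_run_context(run, mp, gsr=False)
        assert ctx.mp_block.shape[1] + 2 * ctx.aux.shape[0] + 1 == 29
        ctx_gsr = make_run_context(run, mp, gsr=True)
        assert ctx_gsr.mp_block.shape[1] + 2 * ctx_gsr.aux.shape[0] + 1 == 31


class TestPipelineEndToEnd:
    def test_multi_mask_equals_single_mask(self, small_dataset):
        sim = small_dataset.runs[("sub000", "run0")]
        ctx = make_run_context(sim.ts, sim.motion)
        rng = np.random.default_rng(11)
        masks = [rng.random(300) > p for p in (0.0, 0.1, 0.2)]
        batch = censored_z_multi(ctx, masks)
        for m, keep in enumerate(masks):
            assert np.allclose(batch[m], censored_z(ctx, keep), atol=1e-12)

    def test_truth_recovery_without_artifact(self):
        # clean generator + full pipeline: group mean z unbiased for the
        # known ground truth (within 3 standard errors per pair)
        cfg = SynthConfig(n_subjects=200, runs_per_subject=1, T=300, n_roi=6,
                          artifact_coupling=0.0, seed=21)
        ds = simulate_dataset(cfg)
        _, Z = dataset_rsfc(ds.runs)
        bias = Z.mean(axis=0) - ds.ground_truth_z
        se = Z.std(axis=0, ddof=1) / np.sqrt(Z.shape[0])
        # 3.5 SE per pair: ~3-sigma criterion corrected for testing 15 pairs
        assert np.all(np.abs(bias) < 3.5 * se)
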