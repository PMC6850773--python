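"""Lagged Gaussian encoding models: lag selection, fitting, cross-validation,
and cross-epoch transfer."""

import numpy as np
import pytest

from novelsupp import (
    SimConfig,
    best_lag,
    build_design,
    cross_validate,
    fit_encoding_model,
    fit_glm,
    simulate_behavior,
    simulate_traces,
    single_variable_models,
    transfer_evaluate,
)
from novelsupp.pipeline import analyze_session


@pytest.fixture(scope="module")
def glm_session():
    cfg = SimConfig(epoch_durations=(120, 240, 120), seed=21, n_cells=4)
    b = simulate_behavior(cfg)
    raw, _, truth, fb = simulate_traces(b, cfg)
    dffm, _ = analyze_session(raw, fb, apply_skew_filter=False)
    return {"fb": fb, "dff": dffm.values, "truth": truth, "cfg": cfg}


class TestBestLag:
    def test_identical_series_lag_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 500)
        res = best_lag(x, x, frame_rate=10.0)
        assert res.lag_frames == 0 and res.peak_r == pytest.approx(1.0)

    def test_shifted_series_recovers_lag(self):
        rng = np.random.default_rng(1)
        x = np.convolve(rng.normal(0, 1, 1000), np.ones(20) / 20, mode="same")
        y = np.roll(x, 5)  # x leads y by 5 frames = 0.5 s at 10 Hz
        res = best_lag(x[50:-50], y[50:-50], frame_rate=10.0)
        assert res.lag_frames == 5 and res.lag_s == pytest.approx(0.5)

    def test_anticorrelated_negative_peak(self):
        rng = np.random.default_rng(2)
        x = np.convolve(rng.normal(0, 1, 1000), np.ones(20) / 20, mode="same")
        y = -np.roll(x, 10)
        res = best_lag(x[50:-50], y[50:-50], frame_rate=10.0)
        assert res.lag_frames == 10 and res.peak_r < -0.9

    def test_zero_variance_flagged(self):
        res = best_lag(np.ones(100), np.arange(100.0), frame_rate=10.0)
        assert res.degenerate and res.lag_s == 0.0


class TestBuildDesign:
    def test_zero_lags_reproduce_regressors(self):
        regs = {"a": np.arange(10.0), "b": np.ones(10)}
        X, names, n_drop = build_design(regs, {"a": 0, "b": 0})
        assert n_drop == 0
        assert np.array_equal(X[:, 0], regs["a"]) and np.all(X[:, -1] == 1.0)

    def test_lagged_column_is_shifted_series(self):
        x = np.arange(20.0)
        X, _, n_drop = build_design({"a": x, "b": x}, {"a": 2, "b": 0})
        assert n_drop == 2
        assert np.array_equal(X[:, 0], x[:-2])  # delayed by 2
        assert np.array_equal(X[:, 1], x[2:])

    def test_row_count_bookkeeping(self):
        x = np.arange(50.0)
        X, _, _ = build_design({"a": x, "b": x, "c": x}, {"a": 3, "b": 7, "c": 0})
        assert X.shape == (43, 4)

    def test_lag_longer_than_series_raises(self):
        with pytest.raises(ValueError):
            build_design({"a": np.arange(5.0)}, {"a": 10})


class TestFitGlm:
    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(0, 1, (2, 200))
        y = 0.5 * x1 - 0.3 * x2 + 2.0
        X = np.column_stack([x1, x2, np.ones(200)])
        w, deficient = fit_glm(X, y)
        assert not deficient
        assert np.allclose(w, [0.5, -0.3, 2.0], atol=1e-12)

    def test_intercept_only_response(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.normal(0, 1, 100), np.ones(100)])
        w, _ = fit_glm(X, np.full(100, 3.0))
        assert w[0] == pytest.approx(0.0, abs=1e-12) and w[1] == pytest.approx(3.0)

    def test_rank_deficient_flagged(self):
        x = np.arange(10.0)
        X = np.column_stack([x, 2 * x, np.ones(10)])
        with pytest.warns(UserWarning, match="rank"):
            _, deficient = fit_glm(X, x)
        assert deficient

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(2)
        n, sigma = 3000, 0.5
        x1, x2 = rng.normal(0, 1, (2, n))
        y = 0.5 * x1 - 0.3 * x2 + 2.0 + rng.normal(0, sigma, n)
        X = np.column_stack([x1, x2, np.ones(n)])
        w, _ = fit_glm(X, y)
        se = sigma / np.sqrt(n)
        assert abs(w[0] - 0.5) < 3 * se and abs(w[1] + 0.3) < 3 * se

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(0, 1, (300, 3)), np.ones(300)])
        y = rng.normal(0, 1, 300)
        w, _ = fit_glm(X, y)
        resid = y - X @ w
        assert np.max(np.abs(X.T @ resid)) < 1e-9 * len(y)


class TestCrossValidate:
    def test_noiseless_linear_response(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(0, 1, 500), np.ones(500)])
        y = 2.0 * X[:, 0] + 1.0
        cv = cross_validate(X, y, k=10)
        assert cv.r2 == pytest.approx(1.0) and cv.rms == pytest.approx(0.0, abs=1e-10)

    def test_independent_response_near_zero_r2(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.normal(0, 1, 2000), np.ones(2000)])
        y = rng.normal(0, 1, 2000)
        cv = cross_validate(X, y, k=10)
        assert cv.r2 < 0.05

    def test_cv_rms_estimates_noise_sigma(self):
        rng = np.random.default_rng(2)
        sigma = 0.7
        X = np.column_stack([rng.normal(0, 1, 4000), np.ones(4000)])
        y = 1.5 * X[:, 0] + rng.normal(0, sigma, 4000)
        cv = cross_validate(X, y, k=10)
        assert cv.rms == pytest.approx(sigma, rel=0.1)

    def test_rms_scales_with_response(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(0, 1, 600), np.ones(600)])
        y = X[:, 0] + rng.normal(0, 0.3, 600)
        c = 5.0
        assert cross_validate(X, c * y).rms == pytest.approx(c * cross_validate(X, y).rms)

    def test_more_folds_than_samples_raises(self):
        with pytest.raises(ValueError):
            cross_validate(np.ones((5, 1)), np.ones(5), k=10)


class TestEncodingPipeline:
    def test_transfer_to_training_epoch_is_near_perfect_noiseless(self):
        cfg = SimConfig(
            epoch_durations=(120, 240, 120), seed=8, n_cells=1, noise_sd=0.0,
            excess_variability=0.0,
        )
        b = simulate_behavior(cfg)
        raw, _, truth, fb = simulate_traces(b, cfg)
        fit = fit_encoding_model(fb, raw[0], train_epoch="Fam", test_epochs=("Fam",))
        # not exactly 1: the latent saturates at high speed (clipped drive)
        # while the model is linear in the raw regressors
        assert fit.transfer["Fam"]["r2"] > 0.95

    def test_suppressed_epoch_overpredicted(self, glm_session):
        # planted suppression decouples activity from behavior in New:
        # transfer r2 drops and the model overpredicts mean activity
        cfg = glm_session["cfg"]
        s = np.ones(4)
        cfg2 = SimConfig(
            epoch_durations=cfg.epoch_durations, seed=5, n_cells=4, suppression=s
        )
        b = simulate_behavior(cfg2)
        raw, _, _, fb = simulate_traces(b, cfg2)
        dffm, _ = analyze_session(raw, fb, apply_skew_filter=False)
        for i in range(4):
            fit = fit_encoding_model(
                fb, dffm.values[i], train_epoch="Fam", test_epochs=("New", "FamPrime")
            )
            assert fit.transfer["New"]["r2"] < fit.transfer["FamPrime"]["r2"]
            assert fit.transfer["New"]["mean_model"] > fit.transfer["New"]["mean_actual"]

    def test_new_trained_fails_when_coupling_abolished(self):
        cfg = SimConfig(epoch_durations=(120, 240, 120), seed=6, n_cells=3, suppression=np.ones(3))
        b = simulate_behavior(cfg)
        raw, _, _, fb = simulate_traces(b, cfg)
        dffm, _ = analyze_session(raw, fb, apply_skew_filter=False)
        for i in range(3):
            fam = fit_encoding_model(fb, dffm.values[i], train_epoch="Fam")
            new = fit_encoding_model(fb, dffm.values[i], train_epoch="New")
            assert new.cv_r2 < 0.05 < 0.5 < fam.cv_r2

    def test_new_trained_comparable_when_coupling_preserved(self):
        cfg = SimConfig(epoch_durations=(120, 240, 120), seed=6, n_cells=3, suppression=np.zeros(3))
        b = simulate_behavior(cfg)
        raw, _, _, fb = simulate_traces(b, cfg)
        dffm, _ = analyze_session(raw, fb, apply_skew_filter=False)
        for i in range(3):
            fam = fit_encoding_model(fb, dffm.values[i], train_epoch="Fam")
            new = fit_encoding_model(fb, dffm.values[i], train_epoch="New")
            assert abs(new.cv_r2 - fam.cv_r2) < 0.2

    def test_fit_deterministic(self, glm_session):
        f1 = fit_encoding_model(glm_session["fb"], glm_session["dff"][0], train_epoch="Fam")
        f2 = fit_encoding_model(glm_session["fb"], glm_session["dff"][0], train_epoch="Fam")
        assert np.array_equal(f1.weights, f2.weights) and f1.cv_r2 == f2.cv_r2

    def test_planted_lag_and_gain_recovered(self):
        lag_true = 0.9
        cfg = SimConfig(
            epoch_durations=(420, 60, 60),
            seed=13,
            n_cells=1,
            suppression=np.zeros(1),
            lag=np.array([lag_true]),
            noise_sd=0.02,
        )
        b = simulate_behavior(cfg)
        raw, _, truth, fb = simulate_traces(b, cfg)
        dffm, _ = analyze_session(raw, fb, apply_skew_filter=False)
        from novelsupp.synthetic import normalized_speed

        shat = normalized_speed(fb.speed)
        res = best_lag(shat[fb.epoch == 0], dffm.values[0][fb.epoch == 0], fb.frame_rate)
        assert abs(res.lag_s - lag_true) <= 1.0 / fb.frame_rate + 1e-9


class TestSingleVariable:
    def test_forward_speed_only_activity(self):
        rng = np.random.default_rng(4)
        cfg = SimConfig(epoch_durations=(240, 60, 60), seed=17, n_cells=1)
        b = simulate_behavior(cfg)
        _, _, _, fb = simulate_traces(b, cfg)
        y = fb.forward_speed + rng.normal(0, 0.1 * fb.forward_speed.std(), fb.n_frames)
        out = single_variable_models(fb, y, train_epoch="Fam")
        assert out["forward_speed"]["cv_r2"] == max(
            v["cv_r2"] for v in out.values() if np.isfinite(v["cv_r2"])
        )
        assert out["reward"]["cv_r2"] < 0.2

    def test_full_model_at_least_best_single(self):
        cfg = SimConfig(epoch_durations=(240, 60, 60), seed=18, n_cells=1)
        b = simulate_behavior(cfg)
        raw, _, _, fb = simulate_traces(b, cfg)
        dffm, _ = analyze_session(raw, fb, apply_skew_filter=False)
        y = dffm.values[0]
        full = fit_encoding_model(fb, y, train_epoch="Fam")
        singles = single_variable_models(fb, y, train_epoch="Fam")
        best_single = np.nanmax([v["cv_r2"] for v in singles.values()])
        assert full.cv_r2 >= best_single - 0.05

    def test_constant_regressor_flagged(self):
        cfg = SimConfig(epoch_durations=(60, 60, 60), seed=19, n_cells=1, task="no_task")
        b = simulate_behavior(cfg)
        raw, _, _, fb = simulate_traces(b, cfg)
        # vr_speed is identically zero inside NoTask
        out = single_variable_models(fb, raw[0], train_epoch="NoTask", regressors=("vr_speed",))
        assert out["vr_speed"]["degenerate"]
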