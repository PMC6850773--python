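"""Ground-truth validation experiments.

Each function sets up a controlled synthetic experiment, runs the relevant
part of the analysis pipeline, and returns summary numbers that can be
checked against the planted ground truth.  Parameter-recovery experiments
hold task proficiency equal across epochs: the suppression index is an
epoch-ratio statistic, so it is validated under its own assumption of
epoch-stationary behavior (epoch-dependent behavior is exercised separately
by the encoding-model experiments, where it is the phenomenon of interest).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .glm import fit_encoding_model
from .pipeline import (
    DEFAULT_RECOVERY_SCHEDULE,
    NO_RECOVERY_SCHEDULE,
    analyze_session,
    simulate_cohort,
)
from .preprocess import detect_rois, motion_correct, sliding_percentile
from .stats import holm_correction
from .suppression import aggregate_suppression
from .synthetic import MovieConfig, SimConfig, simulate_behavior, simulate_movie, simulate_traces

MATCHED_PROFICIENCY = (0.9, 0.9, 0.9)


def dff_oracle_check(
    n_traces: int = 50,
    n_frames: int = 10_000,
    frame_rate: float = 7.8,
    window_s: float = 300.0,
    percentile: float = 8.0,
    seed: int = 0,
    n_full: int = 5,
    n_spot_frames: int = 150,
) -> float:
    """Compare the sliding-percentile baseline against brute force.

    The brute force materializes the truncated window around each frame
    explicitly and calls ``np.percentile``.  The first ``n_full`` traces are
    checked at every frame; the rest at ``n_spot_frames`` random frames each
    (the full check is O(n * window) per trace).  Returns the maximum
    absolute difference over all comparisons.
    """
    rng = np.random.default_rng(seed)
    w = int(round(window_s * frame_rate))
    half = max(w // 2, 1)
    worst = 0.0
    for k in range(n_traces):
        x = rng.normal(100.0, 10.0, n_frames) + 30.0 * np.abs(
            np.sin(np.arange(n_frames) / 500.0 + k)
        )
        got = sliding_percentile(x, w, percentile)
        if k < n_full:
            frames = np.arange(n_frames)
        else:
            frames = rng.integers(0, n_frames, n_spot_frames)
        for t in frames:
            ref = np.percentile(x[max(0, t - half) : min(n_frames, t + half + 1)], percentile)
            worst = max(worst, abs(got[t] - ref))
    return worst


def recovery_experiment(n_mice: int = 8, n_cells: int = 20, seed: int = 0):
    """Single-session-per-mouse suppression recovery at default noise.

    Returns ``(frac_within_005, abs_errors)`` over all cells of all mice.
    """
    errs = []
    for m in range(n_mice):
        cfg = SimConfig(seed=seed * 1009 + m, n_cells=n_cells, proficiency=MATCHED_PROFICIENCY)
        behavior = simulate_behavior(cfg)
        raw, _, truth, fb = simulate_traces(behavior, cfg)
        _, table = analyze_session(
            raw, fb, truth_s=truth.suppression, apply_skew_filter=False, mouse=f"m{m}"
        )
        errs.append((table["S"] - table["truth_s"]).abs().to_numpy())
    err = np.concatenate(errs)
    return float(np.mean(err <= 0.05)), err


def trajectory_experiment(
    n_mice: int = 8,
    n_cells: int = 20,
    n_days: int = 5,
    schedule: tuple = DEFAULT_RECOVERY_SCHEDULE,
    task: str = "task",
    seed: int = 0,
):
    """Grand-mean recovered-vs-planted suppression per day (two-stage means).

    Returns ``(days, recovered, planted)`` arrays.
    """
    base = SimConfig(proficiency=MATCHED_PROFICIENCY, task=task)
    table = simulate_cohort(
        n_mice=n_mice,
        n_cells=n_cells,
        n_days=n_days,
        base_config=base,
        recovery_schedule=schedule,
        proficiency_schedule=(MATCHED_PROFICIENCY[1],) * n_days,
        context="NoTask" if task == "no_task" else "New1",
        seed=seed,
    )
    _, grand = aggregate_suppression(table, "S")
    _, grand_truth = aggregate_suppression(table.assign(S=table["truth_s"]), "S")
    days = grand["day"].to_numpy()
    return days, grand["grand_S"].to_numpy(), grand_truth["grand_S"].to_numpy()


def glm_transfer_experiment(abolished: bool, n_cells: int = 12, seed: int = 0) -> dict:
    """Fam-trained models transferred into New: the qualitative encoding test.

    With behavior-activity coupling abolished in the middle epoch
    (suppression 1), transfer into New should fail while Fam' transfer holds,
    and the model should overpredict (mean modeled > mean actual).  The
    control preserves coupling (suppression 0).  Also fits New-trained models
    to probe whether any behavioral model can explain New activity.
    """
    s = 1.0 if abolished else 0.0
    cfg = SimConfig(seed=seed, n_cells=n_cells, suppression=np.full(n_cells, s))
    behavior = simulate_behavior(cfg)
    raw, _, truth, fb = simulate_traces(behavior, cfg)
    dffm, _ = analyze_session(raw, fb, apply_skew_filter=False)
    r2_new, r2_famprime, overpredict = [], [], []
    cv_fam, cv_new = [], []
    for i in range(n_cells):
        fit = fit_encoding_model(
            fb, dffm.values[i], cell=i, train_epoch="Fam", test_epochs=("New", "FamPrime")
        )
        r2_new.append(fit.transfer["New"]["r2"])
        r2_famprime.append(fit.transfer["FamPrime"]["r2"])
        overpredict.append(
            fit.transfer["New"]["mean_model"] - fit.transfer["New"]["mean_actual"]
        )
        cv_fam.append(fit.cv_r2)
        fit_new = fit_encoding_model(fb, dffm.values[i], cell=i, train_epoch="New")
        cv_new.append(fit_new.cv_r2)
    r2_new, r2_famprime = np.array(r2_new), np.array(r2_famprime)
    return {
        "frac_new_worse": float(np.mean(r2_new < r2_famprime)),
        "mean_r2_new": float(np.nanmean(r2_new)),
        "mean_r2_famprime": float(np.nanmean(r2_famprime)),
        "mean_overprediction": float(np.mean(overpredict)),
        "mean_cv_r2_fam_trained": float(np.nanmean(cv_fam)),
        "mean_cv_r2_new_trained": float(np.nanmean(cv_new)),
    }


def consistency_experiment(
    shared: bool, n_seeds: int = 20, n_cells: int = 20, seed: int = 0
) -> dict:
    """Suppression consistency across two exposures (New 1 vs New 2).

    Per seed, two sessions are simulated with the same cells; with ``shared``
    the planted s_i is reused in both, otherwise drawn independently.  The
    recovered percent-change correlation is compared with the
    attenuation-formula prediction ``var(s) / (var(s) + var(noise))`` where
    the measurement-noise variance is estimated from recovered-minus-planted
    residuals.
    """
    rng = np.random.default_rng(seed)
    rs, preds = [], []
    for k in range(n_seeds):
        s1 = rng.uniform(-0.2, 0.8, n_cells)
        s2 = s1 if shared else rng.uniform(-0.2, 0.8, n_cells)
        # the same physical cells in both exposures: one draw of coupling params
        gain = rng.uniform(0.8, 1.6, n_cells)
        sign = np.where(rng.random(n_cells) < 0.8, 1.0, -1.0)
        lag = rng.uniform(0.0, 1.0, n_cells)
        base = rng.uniform(50.0, 200.0, n_cells)
        rec = []
        resid_var = []
        for j, s in enumerate((s1, s2)):
            cfg = SimConfig(
                seed=int(rng.integers(2**31 - 1)),
                n_cells=n_cells,
                suppression=s,
                locomotion_gain=gain,
                locomotion_sign=sign,
                lag=lag,
                base=base,
                proficiency=MATCHED_PROFICIENCY,
            )
            behavior = simulate_behavior(cfg)
            raw, _, truth, fb = simulate_traces(behavior, cfg)
            _, table = analyze_session(
                raw, fb, truth_s=truth.suppression, apply_skew_filter=False
            )
            rec.append(table["S"].to_numpy())
            resid_var.append(np.var(table["S"].to_numpy() - s))
        r = np.corrcoef(rec[0], rec[1])[0, 1]
        rs.append(r)
        var_s = np.var(s1)
        preds.append(var_s / (var_s + np.mean(resid_var)))
    return {
        "mean_r": float(np.mean(rs)),
        "mean_attenuation_prediction": float(np.mean(preds)),
        "per_seed_r": np.array(rs),
    }


def roi_experiment(seed: int = 0, n_cells: int = 20):
    """Planted-movie ROI detection: recall, precision, and shift recovery."""
    cfg = SimConfig(
        epoch_durations=(30.0, 60.0, 30.0), seed=seed, n_cells=n_cells, frame_rate=7.8
    )
    behavior = simulate_behavior(cfg)
    stack, planted, _, _ = simulate_movie(behavior, cfg)
    rois = detect_rois(stack, px_size_um=1.0)
    det = rois.centroids_um()
    pl = planted["centroids_px"] * planted["px_size_um"]
    matched_planted = 0
    used: set = set()
    for c in pl:
        if len(det) == 0:
            break
        d = np.hypot(det[:, 0] - c[0], det[:, 1] - c[1])
        order = np.argsort(d)
        for j in order:
            if d[j] >= 3.0:
                break
            if j not in used:
                matched_planted += 1
                used.add(j)
                break
    recall = matched_planted / n_cells
    precision = matched_planted / len(det) if len(det) else 0.0

    # planted integer shifts recovered exactly
    rng = np.random.default_rng(seed + 1)
    n_frames = stack.shape[0]
    shifts = rng.integers(-4, 5, size=(n_frames, 2))
    shifts[:100] = 0
    stack2, _, _, _ = simulate_movie(behavior, cfg, MovieConfig(shifts=shifts))
    res = motion_correct(stack2)
    shift_err = int(np.abs(res.shifts - shifts).max())
    return {"recall": recall, "precision": precision, "max_shift_error_px": shift_err}


def holm_null_type1(
    n_reps: int = 10_000, m: int = 6, n: int = 10, alpha: float = 0.05, seed: int = 0
) -> float:
    """Family-wise type-I error of Holm-corrected one-sample t-tests under the null."""
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, (n_reps, m, n))
    t = x.mean(axis=2) / (x.std(axis=2, ddof=1) / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    any_reject = 0
    for row in p:
        _, rej = holm_correction(row, alpha)
        any_reject += bool(rej.any())
    return any_reject / n_reps
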