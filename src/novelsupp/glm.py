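"""Per-cell Gaussian identity-link encoding models on lagged behavioral regressors.

Each cell's ΔF/F is modeled as a linear combination of time-lagged behavior
series (forward/rotational ball speed, reward impulses, VR position and
speed).  The lag of each regressor (0-2 s, behavior leading activity) is the
peak of its normalized cross-correlation with the cell's activity.  A
Gaussian GLM with identity link is ordinary least squares; within-epoch fits
are scored by 10-fold cross-validation (contiguous folds) and cross-epoch
transfer applies the trained weights and lags to a test epoch's behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .behavior import FrameBehavior

REGRESSOR_NAMES = ("forward_speed", "rot_speed", "reward", "vr_position", "vr_speed")


@dataclass
class LagResult:
    lag_s: float
    lag_frames: int
    peak_r: float  # signed Pearson r at the chosen lag
    degenerate: bool = False


@dataclass
class CvResult:
    rms: float
    r2: float
    fold_rms: np.ndarray
    fold_r2: np.ndarray


@dataclass
class GlmFit:
    """A fitted per-cell encoding model and its evaluation metrics."""

    cell: int
    train_epoch: str
    regressors: tuple
    lags_s: dict
    weights: np.ndarray  # one per regressor, training order
    intercept: float
    cv_rms: float
    cv_r2: float
    transfer: dict = field(default_factory=dict)  # epoch -> {"rms":, "r2":}
    rank_deficient: bool = False


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def best_lag(x: np.ndarray, y: np.ndarray, frame_rate: float, max_lag_s: float = 2.0) -> LagResult:
    """Lag in [0, max_lag] maximizing |Pearson r| between ``x`` (behavior,
    leading) and ``y`` (activity); the signed peak correlation is recorded."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must be frame-aligned and equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        return LagResult(0.0, 0, np.nan, degenerate=True)
    max_lag = int(round(max_lag_s * frame_rate))
    best = (0, 0.0)
    for lag in range(0, max_lag + 1):
        if len(x) - lag < 3:
            break
        r = _pearson(x[: len(x) - lag] if lag else x, y[lag:])
        if np.isfinite(r) and abs(r) > abs(best[1]):
            best = (lag, r)
    return LagResult(best[0] / frame_rate, best[0], best[1])


def build_design(
    regressors: dict, lags_frames: dict, intercept: bool = True
) -> tuple[np.ndarray, np.ndarray, int]:
    """Design matrix of lagged regressors.

    Column ``j`` holds regressor ``j`` delayed by its lag; the leading
    ``max(lag)`` frames, which lack full history, are dropped consistently
    from every column.  Returns ``(X, names, n_dropped)``; the intercept is
    the last column when requested.
    """
    names = list(regressors)
    n = len(next(iter(regressors.values())))
    max_lag = max(lags_frames.get(k, 0) for k in names) if names else 0
    if max_lag >= n:
        raise ValueError("lag exceeds series length")
    cols = []
    for k in names:
        x = np.asarray(regressors[k], float)
        if len(x) != n:
            raise ValueError("regressors must have equal length")
        lag = int(lags_frames.get(k, 0))
        cols.append(x[max_lag - lag : n - lag])
    if intercept:
        cols.append(np.ones(n - max_lag))
    return np.column_stack(cols), np.array(names), max_lag


def fit_glm(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Least-squares solution of the Gaussian identity-link GLM.

    Returns ``(weights, rank_deficient)``; a rank-deficient design yields the
    minimum-norm solution and is flagged.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many rows as columns")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in design or response")
    w, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    deficient = rank < X.shape[1]
    if deficient:
        warnings.warn("rank-deficient design; minimum-norm solution returned")
    return w, deficient


def cross_validate(
    X: np.ndarray, y: np.ndarray, k: int = 10, contiguous: bool = True
) -> CvResult:
    """k-fold cross-validation; folds are contiguous blocks by default
    (temporal data), interleaved otherwise."""
    n = len(y)
    if k > n:
        raise ValueError("more folds than samples")
    idx = np.arange(n)
    folds = np.array_split(idx, k) if contiguous else [idx[i::k] for i in range(k)]
    rms = np.empty(k)
    r2 = np.empty(k)
    for i, test in enumerate(folds):
        train = np.setdiff1d(idx, test)
        w, _ = fit_glm(X[train], y[train])
        pred = X[test] @ w
        rms[i] = np.sqrt(np.mean((pred - y[test]) ** 2))
        r = _pearson(pred, y[test])
        r2[i] = r * r if np.isfinite(r) else np.nan
    return CvResult(
        rms=float(np.nanmean(rms)), r2=float(np.nanmean(r2)), fold_rms=rms, fold_r2=r2
    )


def transfer_evaluate(
    fit: GlmFit, regressors_test: dict, y_test: np.ndarray, frame_rate: float
) -> dict:
    """Apply a trained model (weights and lags unchanged) to a test epoch.

    Scores RMS error and squared Pearson correlation over the whole resulting
    series.  Also reports the mean of the modeled and actual traces, since a
    suppressed epoch shows ``mean(model) > mean(actual)``.
    """
    lags_frames = {k: int(round(fit.lags_s[k] * frame_rate)) for k in fit.regressors}
    sub = {k: regressors_test[k] for k in fit.regressors}
    X, _, n_drop = build_design(sub, lags_frames)
    y = np.asarray(y_test, float)[n_drop:]
    if len(y) != X.shape[0]:
        raise ValueError("test series shorter than max lag")
    w = np.concatenate([fit.weights, [fit.intercept]])
    pred = X @ w
    r = _pearson(pred, y)
    return {
        "rms": float(np.sqrt(np.mean((pred - y) ** 2))),
        "r2": float(r * r) if np.isfinite(r) else np.nan,
        "mean_model": float(pred.mean()),
        "mean_actual": float(y.mean()),
    }


def fit_encoding_model(
    fb: FrameBehavior,
    y: np.ndarray,
    cell: int = 0,
    train_epoch: str = "Fam",
    test_epochs: tuple = (),
    regressors: tuple = REGRESSOR_NAMES,
    max_lag_s: float = 2.0,
    k: int = 10,
    contiguous: bool = True,
) -> GlmFit:
    """Full per-cell pipeline: choose lags in the training epoch, fit, 10-fold
    cross-validate, then transfer to each test epoch with lags unchanged."""
    reg_all = fb.regressors()
    mask = fb.epoch_mask(train_epoch)
    y = np.asarray(y, float)
    lags = {}
    degenerate = set()
    for name in regressors:
        res = best_lag(reg_all[name][mask], y[mask], fb.frame_rate, max_lag_s)
        lags[name] = res.lag_s
        if res.degenerate:
            degenerate.add(name)
    lags_frames = {kk: int(round(v * fb.frame_rate)) for kk, v in lags.items()}
    sub = {kk: reg_all[kk][mask] for kk in regressors}
    X, names, n_drop = build_design(sub, lags_frames)
    y_train = y[mask][n_drop:]
    cv = cross_validate(X, y_train, k=k, contiguous=contiguous)
    w, deficient = fit_glm(X, y_train)
    fit = GlmFit(
        cell=cell,
        train_epoch=train_epoch,
        regressors=tuple(regressors),
        lags_s=lags,
        weights=w[:-1],
        intercept=float(w[-1]),
        cv_rms=cv.rms,
        cv_r2=cv.r2,
        rank_deficient=deficient,
    )
    for ep in test_epochs:
        m = fb.epoch_mask(ep)
        fit.transfer[ep] = transfer_evaluate(
            fit, {kk: reg_all[kk][m] for kk in regressors}, y[m], fb.frame_rate
        )
    return fit


def single_variable_models(
    fb: FrameBehavior,
    y: np.ndarray,
    train_epoch: str = "Fam",
    regressors: tuple = REGRESSOR_NAMES,
    max_lag_s: float = 2.0,
    k: int = 10,
) -> dict:
    """One model per regressor (own lag plus intercept); metrics per regressor.

    A constant regressor yields NaN metrics flagged as degenerate.
    """
    out = {}
    for name in regressors:
        try:
            fit = fit_encoding_model(
                fb, y, train_epoch=train_epoch, regressors=(name,), max_lag_s=max_lag_s, k=k
            )
            degen = np.std(fb.regressors()[name][fb.epoch_mask(train_epoch)]) == 0
            out[name] = {
                "cv_rms": fit.cv_rms,
                "cv_r2": np.nan if degen else fit.cv_r2,
                "lag_s": fit.lags_s[name],
                "degenerate": bool(degen),
            }
        except ValueError:
            out[name] = {"cv_rms": np.nan, "cv_r2": np.nan, "lag_s": np.nan, "degenerate": True}
    return out
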