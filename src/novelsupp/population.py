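"""Population-level correlation structure, cross-context consistency, and
cell classification.

These analyses ask whether suppression is coordinated across the population:
short-time pairwise correlations track moment-to-moment co-fluctuation, the
cell-cell correlation matrix tests whether activity relationships between
cells survive a context switch, and per-cell suppression is compared across
contexts (New 1 vs New 2 vs No Task) and against anatomical distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from scipy.stats import pearsonr


@dataclass
class PairwiseCorrMatrix:
    matrix: np.ndarray
    epoch: str
    n_frames: int


@dataclass
class ConsistencyResult:
    context_pair: tuple
    r: float
    p: float
    mean_abs_diff: float
    n_cells: int
    pairs: np.ndarray  # (n_cells, 2) per-cell percent-change pairs


def _pearson(a, b):
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def behavior_activity_correlation(
    x: np.ndarray, y: np.ndarray, frame_rate: float, window_s: float = 2.0
):
    """Signed cross-correlation peak between demeaned series within +/-
    ``window_s`` of lag.  Returns ``(r_at_peak, lag_s)``; positive lag means
    ``x`` leads ``y``.  NaN on zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    max_lag = int(round(window_s * frame_rate))
    best = (0, 0.0)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = x[: len(x) - lag] if lag else x, y[lag:]
        else:
            a, b = x[-lag:], y[: len(y) + lag]
        if len(a) < 3:
            continue
        r = _pearson(a, b)
        if np.isfinite(r) and abs(r) > abs(best[1]):
            best = (lag, r)
    return best[1], best[0] / frame_rate


def short_time_population_correlation(
    dff: np.ndarray, frame_rate: float, window_s: float = 5.0
) -> np.ndarray:
    """Mean pairwise Pearson correlation in non-overlapping ``window_s`` bins.

    Pairs with zero within-bin variance are skipped; a bin where every pair is
    degenerate is NaN.
    """
    dff = np.atleast_2d(np.asarray(dff, float))
    n_cells, n_frames = dff.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    w = int(round(window_s * frame_rate))
    if w < 2:
        raise ValueError("window shorter than 2 frames")
    n_bins = n_frames // w
    out = np.full(n_bins, np.nan)
    iu = np.triu_indices(n_cells, k=1)
    for b in range(n_bins):
        seg = dff[:, b * w : (b + 1) * w]
        sd = seg.std(axis=1)
        ok = sd > 0
        if np.count_nonzero(ok) < 2:
            continue
        z = (seg[ok] - seg[ok].mean(axis=1, keepdims=True)) / (
            seg[ok].std(axis=1, keepdims=True) * np.sqrt(seg.shape[1])
        )
        c = z @ z.T
        iu_ok = np.triu_indices(np.count_nonzero(ok), k=1)
        out[b] = float(c[iu_ok].mean())
    return out


def pairwise_corr_matrix(dff: np.ndarray, epoch_mask: np.ndarray, epoch: str = "") -> PairwiseCorrMatrix:
    """Cells x cells Pearson matrix over one epoch's frames."""
    seg = np.asarray(dff, float)[:, np.asarray(epoch_mask, bool)]
    with np.errstate(invalid="ignore"):
        m = np.corrcoef(seg)
    np.fill_diagonal(m, 1.0)
    return PairwiseCorrMatrix(matrix=m, epoch=epoch, n_frames=seg.shape[1])


def structure_stability(a: PairwiseCorrMatrix, b: PairwiseCorrMatrix) -> tuple[float, float]:
    """Pearson r (and p) between the strict upper triangles of two cell-cell
    correlation matrices; the cell set and order must match."""
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("matrices must share the cell set and ordering")
    n = a.matrix.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells")
    iu = np.triu_indices(n, k=1)
    r, p = pearsonr(a.matrix[iu], b.matrix[iu])
    return float(r), float(p)


def suppression_consistency(
    table, context_a: str, context_b: str, day: int | None = None
) -> ConsistencyResult:
    """Correlate per-cell percent change between two contexts (shared cells)."""
    t = table if day is None else table[table["day"] == day]
    a = t[t["context"] == context_a].set_index("cell")["percent_change"]
    b = t[t["context"] == context_b].set_index("cell")["percent_change"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared cells")
    va, vb = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    r, p = pearsonr(va, vb)
    return ConsistencyResult(
        context_pair=(context_a, context_b),
        r=float(r),
        p=float(p),
        mean_abs_diff=float(np.mean(np.abs(va - vb))),
        n_cells=len(shared),
        pairs=np.column_stack([va, vb]),
    )


def mean_abs_difference(table, context_a: str, context_b: str, day: int | None = None) -> float:
    return suppression_consistency(table, context_a, context_b, day).mean_abs_diff


def stratify_by_initial_suppression(table, n_strata: int = 4, value: str = "percent_change"):
    """Assign cells to Day-1 quantile strata and average each stratum per day.

    Returns ``(per_stratum, assignment)``: a day x stratum table of mean
    values and the per-cell stratum labels.  Stratum 0 is the most negative
    (most suppressed) quartile of Day-1 percent change.
    """
    day1 = table[table["day"] == table["day"].min()].set_index("cell")[value]
    if len(day1) < n_strata:
        raise ValueError("fewer cells than strata")
    q = np.quantile(day1.to_numpy(), np.linspace(0, 1, n_strata + 1))
    q[0], q[-1] = -np.inf, np.inf
    labels = np.clip(np.searchsorted(q, day1.to_numpy(), side="right") - 1, 0, n_strata - 1)
    assignment = dict(zip(day1.index, labels))
    t = table[table["cell"].isin(day1.index)].copy()
    t["stratum"] = t["cell"].map(assignment)
    per_stratum = t.pivot_table(index="day", columns="stratum", values=value, aggfunc="mean")
    return per_stratum, assignment


def distance_analyses(centroids_um: np.ndarray, percent_change: np.ndarray, dff: np.ndarray):
    """Pairwise anatomical distance vs suppression difference and activity
    correlation.

    Returns a dict with Pearson r and p for (distance, |Δ percent change|)
    and (distance, pairwise activity r).  All-coincident centroids are
    degenerate and flagged with NaN results.
    """
    cent = np.asarray(centroids_um, float)
    n = len(cent)
    if n < 3:
        raise ValueError("need at least 3 cells")
    iu = np.triu_indices(n, k=1)
    dist = np.hypot(cent[:, 0][:, None] - cent[:, 0], cent[:, 1][:, None] - cent[:, 1])[iu]
    ds = np.abs(percent_change[:, None] - percent_change)[iu]
    act = np.corrcoef(np.asarray(dff, float))[iu]
    if np.std(dist) == 0:
        return {
            "r_dist_dsupp": np.nan, "p_dist_dsupp": np.nan,
            "r_dist_actcorr": np.nan, "p_dist_actcorr": np.nan,
            "degenerate": True,
        }
    r1, p1 = pearsonr(dist, ds)
    r2, p2 = pearsonr(dist, act)
    return {
        "r_dist_dsupp": float(r1), "p_dist_dsupp": float(p1),
        "r_dist_actcorr": float(r2), "p_dist_actcorr": float(p2),
        "degenerate": False,
    }


def stop_triggered_average(x: np.ndarray, stop_idx: np.ndarray, half_frames: int) -> np.ndarray:
    """Mean of ``x`` in windows of +/- ``half_frames`` around stop events."""
    segs = [
        x[i - half_frames : i + half_frames + 1]
        for i in stop_idx
        if i - half_frames >= 0 and i + half_frames + 1 <= len(x)
    ]
    if not segs:
        raise ValueError("no stop event has a full window")
    return np.mean(segs, axis=0)


def classify_locomotion_phase(
    dff_row: np.ndarray,
    speed: np.ndarray,
    stop_idx: np.ndarray,
    frame_rate: float,
    window_s: float = 5.0,
    min_stops: int = 5,
):
    """Classify a cell as locomotion- or immobility-correlated by Hilbert phase.

    Stop-triggered mean activity and speed (windows +/- ``window_s`` around
    stops) are cross-correlated; the phase of the analytic signal (Hilbert
    transform) of that cross-correlation at zero lag classifies the cell:
    phase in (-pi/2, pi/2] means locomotion-correlated, otherwise
    immobility-correlated.  Returns ``(label, phase_rad)``.
    """
    stop_idx = np.asarray(stop_idx, int)
    half = int(round(window_s * frame_rate))
    if len(stop_idx) < min_stops:
        raise ValueError(f"need at least {min_stops} stop events")
    act = stop_triggered_average(np.asarray(dff_row, float), stop_idx, half)
    spd = stop_triggered_average(np.asarray(speed, float), stop_idx, half)
    if np.std(act) < 1e-12:
        raise ValueError("flat activity; cannot classify")
    a = act - act.mean()
    s = spd - spd.mean()
    xc = np.correlate(a, s, mode="full")
    norm = np.linalg.norm(a) * np.linalg.norm(s)
    if norm > 0:
        xc = xc / norm
    analytic = hilbert(xc)
    phase = float(np.angle(analytic[len(xc) // 2]))  # zero lag
    label = "locomotion" if -np.pi / 2 < phase <= np.pi / 2 else "immobility"
    return label, phase


def detect_stops(speed: np.ndarray, frame_rate: float, thresh: float = 2.0, min_run_s: float = 1.0):
    """Indices where running (speed > thresh sustained) transitions to rest."""
    moving = np.asarray(speed, float) > thresh
    run = int(round(min_run_s * frame_rate))
    stops = []
    count = 0
    for i, m in enumerate(moving):
        if m:
            count += 1
        else:
            if count >= run:
                stops.append(i)
            count = 0
    return np.asarray(stops, int)


def spatial_activity_map(
    dff_row: np.ndarray,
    position: np.ndarray,
    vr_speed_signed: np.ndarray,
    bin_cm: float = 20.0,
    track_length: float = 180.0,
    dead_band: float = 1.0,
    min_occupancy_frames: int = 2,
):
    """Occupancy-weighted mean ΔF/F per track bin, split by running direction.

    Direction is the sign of frame-wise VR displacement with a ``dead_band``
    (cm/s); frames inside the dead band are ignored.  Bins with fewer than
    ``min_occupancy_frames`` frames are NaN.  Returns a (2, n_bins) array,
    row 0 = positive direction, row 1 = negative.
    """
    pos = np.asarray(position, float)
    v = np.asarray(vr_speed_signed, float)
    y = np.asarray(dff_row, float)
    n_bins = int(np.ceil(track_length / bin_cm))
    idx = np.minimum((pos / bin_cm).astype(int), n_bins - 1)
    out = np.full((2, n_bins), np.nan)
    for row, mask in enumerate((v > dead_band, v < -dead_band)):
        if not mask.any():
            continue
        counts = np.bincount(idx[mask], minlength=n_bins)
        sums = np.bincount(idx[mask], weights=y[mask], minlength=n_bins)
        ok = counts >= min_occupancy_frames
        out[row, ok] = sums[ok] / counts[ok]
    return out
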