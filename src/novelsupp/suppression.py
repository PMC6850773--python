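"""Per-cell activity suppression in the middle epoch relative to Fam_Ave.

The suppression index of a cell is ``S = 1 - mu_mid / mean(mu_Fam, mu_Fam')``
where ``mu`` is the mean ΔF/F in an epoch; ``percent_change = -100 * S`` so
that suppressed cells plot negative.  Cohort summaries average cells within
each mouse first and then average mice (two-stage grand mean).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

TABLE_COLUMNS = [
    "cell",
    "mouse",
    "day",
    "context",
    "mu_new",
    "mu_fam",
    "mu_famprime",
    "S",
    "percent_change",
    "truth_s",
]


def epoch_mean_dff(dff_row: np.ndarray, epoch_mask: np.ndarray) -> float:
    """Mean ΔF/F over the masked frames."""
    mask = np.asarray(epoch_mask, bool)
    if not mask.any():
        raise ValueError("empty epoch mask")
    return float(np.mean(np.asarray(dff_row, float)[mask]))


def suppression_index(mu_new: float, mu_fam: float, mu_famprime: float) -> tuple[float, float]:
    """Suppression index ``S`` and ``percent_change = -100 S`` for one cell.

    Raises on a non-positive familiar-epoch mean (the normalization is
    undefined; such cells are excluded upstream).
    """
    fam_ave = 0.5 * (mu_fam + mu_famprime)
    if fam_ave <= 0:
        raise ValueError("non-positive familiar mean; cell cannot be normalized")
    s = 1.0 - mu_new / fam_ave
    return float(s), float(-100.0 * s)


def build_suppression_table(
    dff: np.ndarray,
    epoch: np.ndarray,
    epoch_names: tuple,
    mouse: str = "m0",
    day: int = 1,
    context: str = "New1",
    truth_s: np.ndarray | None = None,
    valid: np.ndarray | None = None,
    famave_mode: str = "mean_of_means",
) -> pd.DataFrame:
    """Per-cell suppression rows for one session.

    ``famave_mode`` selects how Fam_Ave is formed: ``"mean_of_means"``
    (average of the two epoch means; the flanking epochs have equal length so
    this matches the concatenated mean up to frame rounding) or
    ``"concatenated"`` (mean over pooled Fam and Fam' frames).
    """
    masks = {name: epoch == code for code, name in enumerate(epoch_names)}
    fam, midname, famp = epoch_names
    rows = []
    for i in range(dff.shape[0]):
        if valid is not None and not valid[i]:
            continue
        mu_mid = epoch_mean_dff(dff[i], masks[midname])
        mu_f = epoch_mean_dff(dff[i], masks[fam])
        mu_fp = epoch_mean_dff(dff[i], masks[famp])
        if famave_mode == "concatenated":
            mu_eff = epoch_mean_dff(dff[i], masks[fam] | masks[famp])
            mu_f_used, mu_fp_used = mu_eff, mu_eff
        else:
            mu_f_used, mu_fp_used = mu_f, mu_fp
        try:
            s, pct = suppression_index(mu_mid, mu_f_used, mu_fp_used)
        except ValueError:
            warnings.warn(f"cell {i}: non-positive familiar mean, excluded")
            continue
        rows.append(
            {
                "cell": i,
                "mouse": mouse,
                "day": day,
                "context": context,
                "mu_new": mu_mid,
                "mu_fam": mu_f,
                "mu_famprime": mu_fp,
                "S": s,
                "percent_change": pct,
                "truth_s": truth_s[i] if truth_s is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def aggregate_suppression(table: pd.DataFrame, value: str = "S") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage averages: per-mouse means, then a grand mean across mice.

    Returns ``(per_mouse, grand)`` frames indexed by (day, context).  Mice
    with zero valid cells are dropped with a warning.
    """
    if table.empty:
        raise ValueError("empty suppression table")
    t = table.dropna(subset=[value])
    dropped = set(table["mouse"]) - set(t["mouse"])
    if dropped:
        warnings.warn(f"mice with no valid cells dropped: {sorted(dropped)}")
    per_mouse = (
        t.groupby(["day", "context", "mouse"], as_index=False)[value]
        .mean()
        .rename(columns={value: f"mean_{value}"})
    )
    grand = (
        per_mouse.groupby(["day", "context"], as_index=False)[f"mean_{value}"]
        .mean()
        .rename(columns={f"mean_{value}": f"grand_{value}"})
    )
    return per_mouse, grand


def suppression_histogram(
    table: pd.DataFrame, day: int | None = None, bin_width: float = 10.0, value: str = "percent_change"
):
    """Histogram of per-cell percent change, ``bin_width`` percent per bin."""
    t = table if day is None else table[table["day"] == day]
    vals = t[value].dropna().to_numpy()
    if vals.size == 0:
        return np.zeros(0, int), np.zeros(1)
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return counts, edges
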