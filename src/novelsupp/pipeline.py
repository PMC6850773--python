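"""End-to-end analysis pipelines and multi-day cohort simulation.

``analyze_session`` turns raw per-cell fluorescence into a per-cell
suppression table via the standard preprocessing chain (optional neuropil
subtraction, sliding-percentile ΔF/F, skewness filter).  ``simulate_cohort``
generates a multi-mouse, multi-day synthetic cohort with a per-day
suppression schedule and runs every session through the same chain, keeping
the planted ground truth alongside the recovered values.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import suppression as supp
from .behavior import FrameBehavior
from .preprocess import DffMatrix, compute_dff, neuropil_correct, skewness_filter
from .synthetic import SimConfig, simulate_behavior, simulate_traces

# Defaults for the five-day cohort: suppression decays (cells recover) while
# task proficiency in the novel environment climbs; in the No-Task variant
# suppression does not recover.
DEFAULT_RECOVERY_SCHEDULE = (1.0, 0.8, 0.6, 0.45, 0.3)
NO_RECOVERY_SCHEDULE = (1.0, 1.0, 1.0, 1.0, 1.0)
DEFAULT_PROFICIENCY_SCHEDULE = (0.3, 0.5, 0.65, 0.8, 0.9)


def make_dff_matrix(
    raw: np.ndarray,
    frame_rate: float,
    fam_mask: np.ndarray,
    neuropil: np.ndarray | None = None,
    neuropil_r: float = 0.8,
    window_s: float = 300.0,
    percentile: float = 8.0,
    skew_threshold: float = 0.3,
) -> DffMatrix:
    """Raw traces -> neuropil-corrected sliding-percentile ΔF/F with validity flags."""
    n_cells, n_frames = raw.shape
    values = np.empty((n_cells, n_frames))
    f0 = np.empty((n_cells, n_frames))
    valid = np.ones(n_cells, bool)
    reasons = [""] * n_cells
    for i in range(n_cells):
        trace = raw[i]
        if neuropil is not None:
            trace = neuropil_correct(trace, neuropil, r=neuropil_r)
        dff, base, ok = compute_dff(trace, frame_rate, window_s=window_s, percentile=percentile)
        values[i] = dff
        f0[i] = base
        if not ok:
            valid[i] = False
            reasons[i] = "non-positive F0"
            continue
        keep, why = skewness_filter(dff[fam_mask], threshold=skew_threshold)
        if not keep:
            valid[i] = False
            reasons[i] = why
    return DffMatrix(values=values, frame_rate=frame_rate, valid=valid, f0=f0, drop_reason=reasons)


def analyze_session(
    raw: np.ndarray,
    fb: FrameBehavior,
    neuropil: np.ndarray | None = None,
    neuropil_r: float = 0.8,
    mouse: str = "m0",
    day: int = 1,
    context: str = "New1",
    truth_s: np.ndarray | None = None,
    apply_skew_filter: bool = True,
    famave_mode: str = "mean_of_means",
) -> tuple[DffMatrix, pd.DataFrame]:
    """Standard chain: ΔF/F, quality filters, per-cell suppression table."""
    dffm = make_dff_matrix(
        raw,
        fb.frame_rate,
        fam_mask=fb.epoch_mask("Fam"),
        neuropil=neuropil,
        neuropil_r=neuropil_r,
        skew_threshold=0.3 if apply_skew_filter else -np.inf,
    )
    table = supp.build_suppression_table(
        dffm.values,
        fb.epoch,
        fb.epoch_names,
        mouse=mouse,
        day=day,
        context=context,
        truth_s=truth_s,
        valid=dffm.valid,
        famave_mode=famave_mode,
    )
    return dffm, table


def simulate_cohort(
    n_mice: int = 8,
    n_cells: int = 20,
    n_days: int = 5,
    base_config: SimConfig | None = None,
    recovery_schedule: tuple = DEFAULT_RECOVERY_SCHEDULE,
    proficiency_schedule: tuple = DEFAULT_PROFICIENCY_SCHEDULE,
    context: str = "New1",
    seed: int = 0,
    apply_skew_filter: bool = False,
) -> pd.DataFrame:
    """Simulate and analyze a multi-day cohort; returns the suppression table.

    Each mouse draws per-cell parameters once (cells are tracked across days);
    on day ``d`` the planted suppression is ``s_i * recovery_schedule[d]``.
    The truth column stores the day's effective planted value.  The skewness
    filter is off by default here so recovered and planted cells stay in
    one-to-one correspondence; enable it to emulate the real selection step.
    """
    base = base_config or SimConfig()
    tables = []
    for m in range(n_mice):
        cell_cfg = replace(base, n_cells=n_cells, seed=seed * 1009 + m)
        cells = cell_cfg.resolve_cells()
        for d in range(n_days):
            sched = recovery_schedule[min(d, len(recovery_schedule) - 1)]
            prof = proficiency_schedule[min(d, len(proficiency_schedule) - 1)]
            s_day = np.clip(cells["suppression"] * sched, -0.5, 1.0)
            cfg = replace(
                cell_cfg,
                suppression=s_day,
                locomotion_gain=cells["gain"],
                locomotion_sign=cells["sign"],
                lag=cells["lag"],
                base=cells["base"],
                proficiency=(
                    base.proficiency[0],
                    base.proficiency[1] if base.task == "no_task" else prof,
                    base.proficiency[2],
                ),
                seed=(seed * 1009 + m) * 31 + d,
            )
            behavior = simulate_behavior(cfg)
            raw, neuropil, truth, fb = simulate_traces(behavior, cfg)
            _, table = analyze_session(
                raw,
                fb,
                neuropil=None,
                mouse=f"m{m}",
                day=d + 1,
                context=context,
                truth_s=truth.suppression,
                apply_skew_filter=apply_skew_filter,
            )
            tables.append(table)
    return pd.concat(tables, ignore_index=True)


def recovery_error(table: pd.DataFrame) -> pd.Series:
    """Per-row absolute error of recovered S against the planted value."""
    return (table["S"] - table["truth_s"]).abs()
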