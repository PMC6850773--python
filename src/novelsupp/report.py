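"""Report assembly: metrics CSVs, summary figures, and a run manifest."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pipeline import simulate_cohort
from .stats import apply_holm, one_sample_t
from .suppression import aggregate_suppression, suppression_histogram
from .synthetic import SimConfig


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def load_config(path) -> tuple[SimConfig, dict]:
    """Read a declarative YAML key-value file into a SimConfig.

    Keys matching SimConfig fields configure the simulation; the remainder
    (e.g. ``n_mice``, ``n_days``, ``seed``) are returned as report options.
    """
    import dataclasses

    import yaml

    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    field_names = {fld.name for fld in dataclasses.fields(SimConfig)}
    cfg_kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items() if k in field_names}
    options = {k: v for k, v in raw.items() if k not in field_names}
    return SimConfig(**cfg_kwargs), options


def suppression_stats(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-sample t-tests of per-mouse mean S against 0, one family per
    context (days within a context are corrected together, Holm)."""
    per_mouse, _ = aggregate_suppression(table)
    rows = []
    for context, sub in per_mouse.groupby("context"):
        results = []
        for day, day_sub in sub.groupby("day"):
            vals = day_sub["mean_S"].to_numpy()
            if len(vals) < 2:
                continue
            results.append(one_sample_t(vals, 0.0, label=f"{context} day {day} S vs 0"))
        apply_holm(results, alpha)
        for r in results:
            rows.append(
                {
                    "test": r.name,
                    "label": r.label,
                    "statistic": r.statistic,
                    "df": r.df,
                    "p": r.p,
                    "p_holm": r.p_adjusted,
                    "reject": r.reject,
                }
            )
    return pd.DataFrame(rows)


def build_report(
    outdir,
    config: SimConfig | None = None,
    n_mice: int = 4,
    n_cells: int = 15,
    n_days: int = 5,
    seed: int = 0,
    make_figures: bool = True,
) -> dict:
    """Simulate a cohort, write metrics CSVs and figures, return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or SimConfig()
    _log(f"simulating cohort: {n_mice} mice x {n_cells} cells x {n_days} days")
    table = simulate_cohort(
        n_mice=n_mice, n_cells=n_cells, n_days=n_days, base_config=config, seed=seed
    )
    table.to_csv(outdir / "suppression_table.csv", index=False)
    per_mouse, grand = aggregate_suppression(table)
    per_mouse.to_csv(outdir / "per_mouse_suppression.csv", index=False)
    grand.to_csv(outdir / "grand_mean_suppression.csv", index=False)
    stats = suppression_stats(table)
    stats.to_csv(outdir / "stats.csv", index=False)
    _log(f"wrote suppression tables ({len(table)} cell-days)")

    if make_figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        figdir = outdir / "figures"
        figdir.mkdir(exist_ok=True)
        counts, edges = suppression_histogram(table, day=1)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", color="0.4")
        ax.set_xlabel("percent change in ΔF/F (New vs Fam_Ave)")
        ax.set_ylabel("cells")
        ax.set_title("Day 1 suppression")
        fig.tight_layout()
        fig.savefig(figdir / "suppression_histogram_day1.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(grand["day"], -100 * grand["grand_S"], "o-")
        ax.set_xlabel("day")
        ax.set_ylabel("grand mean percent change")
        ax.axhline(0, color="k", lw=0.5)
        fig.tight_layout()
        fig.savefig(figdir / "recovery_curve.png", dpi=120)
        plt.close(fig)
        _log("wrote figures")

    cfg_dict = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in asdict(config).items()
    }
    cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "n_mice": n_mice,
        "n_cells": n_cells,
        "n_days": n_days,
        "config": cfg_dict,
        "config_sha256": cfg_hash,
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
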