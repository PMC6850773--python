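"""Population structure: consistency across exposures and cell classes.

Simulates two novel-environment exposures of the same cells with a shared
planted suppression, correlates the recovered per-cell percent change
(New 1 vs New 2), and classifies cells as locomotion- or
immobility-correlated from the Hilbert phase of their stop-triggered
activity.
"""

import numpy as np

from novelsupp import (
    SimConfig,
    classify_locomotion_phase,
    pairwise_corr_matrix,
    short_time_population_correlation,
    simulate_behavior,
    simulate_traces,
    structure_stability,
    suppression_consistency,
)
from novelsupp.pipeline import analyze_session
from novelsupp.population import detect_stops

rng = np.random.default_rng(3)
n_cells = 12
s_shared = rng.uniform(-0.2, 0.8, n_cells)
tables = []
dffs = {}
for k, ctx in enumerate(("New1", "New2")):
    cfg = SimConfig(n_cells=n_cells, seed=100 + k, suppression=s_shared,
                    proficiency=(0.9, 0.9, 0.9))
    b = simulate_behavior(cfg)
    raw, _, truth, fb = simulate_traces(b, cfg)
    dffm, table = analyze_session(raw, fb, context=ctx, truth_s=truth.suppression,
                                  apply_skew_filter=False)
    tables.append(table)
    dffs[ctx] = (dffm, fb)

import pandas as pd

res = suppression_consistency(pd.concat(tables), "New1", "New2")
print(f"suppression consistency New1 vs New2: r = {res.r:.3f} (p = {res.p:.2g}, "
      f"mean |Δ percent change| = {res.mean_abs_diff:.1f})")

dffm, fb = dffs["New1"]
a = pairwise_corr_matrix(dffm.values, fb.epoch_mask("Fam"), "Fam")
bmat = pairwise_corr_matrix(dffm.values, fb.epoch_mask("New"), "New")
r, p = structure_stability(a, bmat)
print(f"cell-cell correlation structure Fam vs New: r = {r:.3f}")

pop = short_time_population_correlation(dffm.values, fb.frame_rate)
print(f"short-time (5 s) population correlation: mean {np.nanmean(pop):+.3f}")

stops = detect_stops(fb.speed, fb.frame_rate)
labels = []
for i in range(n_cells):
    try:
        label, phase = classify_locomotion_phase(dffm.values[i], fb.speed, stops, fb.frame_rate)
        labels.append(label)
    except ValueError:
        labels.append("unclassifiable")
print("locomotion/immobility classification:",
      {lab: labels.count(lab) for lab in set(labels)})
print("\nA high consistency r means each cell's suppression is a stable,")
print("cell-intrinsic property across different novel environments.")
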