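"""Population correlation structure, consistency, and cell classification."""

import numpy as np
import pandas as pd
import pytest

from novelsupp import (
    behavior_activity_correlation,
    classify_locomotion_phase,
    distance_analyses,
    pairwise_corr_matrix,
    short_time_population_correlation,
    spatial_activity_map,
    stratify_by_initial_suppression,
    structure_stability,
    suppression_consistency,
)
from novelsupp.population import detect_stops, stop_triggered_average
from novelsupp.validation import consistency_experiment


class TestBehaviorActivityCorrelation:
    def test_identical_series(self):
        x = np.random.default_rng(0).normal(0, 1, 400)
        r, lag = behavior_activity_correlation(x, x, frame_rate=10.0)
        assert r == pytest.approx(1.0) and lag == 0.0

    def test_sign_inverted_series(self):
        x = np.random.default_rng(1).normal(0, 1, 400)
        r, lag = behavior_activity_correlation(x, -x, frame_rate=10.0)
        assert r == pytest.approx(-1.0) and lag == 0.0

    def test_shifted_series_found_at_lag(self):
        rng = np.random.default_rng(2)
        x = np.convolve(rng.normal(0, 1, 800), np.ones(15) / 15, mode="same")
        y = np.roll(x, 10)
        r, lag = behavior_activity_correlation(x[30:-30], y[30:-30], frame_rate=10.0)
        assert abs(r) > 0.95 and lag == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        r, lag = behavior_activity_correlation(np.ones(50), np.arange(50.0), 10.0)
        assert np.isnan(r)


class TestShortTimeCorrelation:
    def test_duplicated_traces_give_one_everywhere(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 500)
        out = short_time_population_correlation(np.vstack([x, x, x]), frame_rate=10.0)
        assert np.allclose(out, 1.0)

    def test_anticorrelated_pair_gives_minus_one(self):
        x = np.random.default_rng(1).normal(0, 1, 500)
        out = short_time_population_correlation(np.vstack([x, -x]), frame_rate=10.0)
        assert np.allclose(out, -1.0)

    def test_independent_cells_near_zero(self):
        rng = np.random.default_rng(2)
        dff = rng.normal(0, 1, (10, 5000))  # 100 bins of 50 frames at 10 Hz
        out = short_time_population_correlation(dff, frame_rate=10.0)
        assert len(out) == 100
        assert abs(np.nanmean(out)) < 0.1

    def test_flat_pairs_skipped(self):
        x = np.random.default_rng(3).normal(0, 1, 100)
        dff = np.vstack([x, x, np.zeros(100)])
        out = short_time_population_correlation(dff, frame_rate=10.0)
        assert np.allclose(out, 1.0)  # the flat cell contributes no pairs

    def test_single_cell_raises(self):
        with pytest.raises(ValueError):
            short_time_population_correlation(np.zeros((1, 100)), 10.0)


class TestStructureStability:
    def _mat(self, dff, epoch="e"):
        return pairwise_corr_matrix(dff, np.ones(dff.shape[1], bool), epoch)

    def test_corr_matrix_invariants(self):
        rng = np.random.default_rng(0)
        m = self._mat(rng.normal(0, 1, (6, 300))).matrix
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 1.0)
        assert m.min() >= -1.0 and m.max() <= 1.0

    def test_identical_epochs_give_unit_stability(self):
        rng = np.random.default_rng(1)
        a = self._mat(rng.normal(0, 1, (8, 200)))
        r, _ = structure_stability(a, a)
        assert r == pytest.approx(1.0)

    def test_independent_populations_near_zero(self):
        rng = np.random.default_rng(2)
        a = self._mat(rng.normal(0, 1, (50, 400)))
        b = self._mat(rng.normal(0, 1, (50, 400)))
        r, _ = structure_stability(a, b)
        assert abs(r) < 0.1

    def test_shared_latent_drivers_preserve_structure(self):
        rng = np.random.default_rng(3)
        latent = rng.normal(0, 1, (3, 800))
        w = rng.normal(0, 1, (20, 3))
        a = self._mat(w @ latent[:, :400] + 0.3 * rng.normal(0, 1, (20, 400)))
        b = self._mat(w @ latent[:, 400:] + 0.3 * rng.normal(0, 1, (20, 400)))
        r, _ = structure_stability(a, b)
        assert r > 0.7

    def test_too_few_cells_raises(self):
        a = self._mat(np.random.default_rng(4).normal(0, 1, (2, 100)))
        with pytest.raises(ValueError):
            structure_stability(a, a)


def _consistency_table(pc_a, pc_b, context_b="New2"):
    rows = []
    for c, v in enumerate(pc_a):
        rows.append({"cell": c, "mouse": "A", "day": 1, "context": "New1", "percent_change": v})
    for c, v in enumerate(pc_b):
        rows.append({"cell": c, "mouse": "A", "day": 1, "context": context_b, "percent_change": v})
    return pd.DataFrame(rows)


class TestConsistency:
    def test_identical_vectors(self):
        pc = np.array([-50.0, -20.0, 10.0, -70.0])
        res = suppression_consistency(_consistency_table(pc, pc), "New1", "New2")
        assert res.r == pytest.approx(1.0) and res.mean_abs_diff == 0.0 and res.n_cells == 4

    def test_attenuation_formula_prediction(self):
        # shared s plus independent noise: E[r] = var(s) / (var(s)+var(noise))
        rng = np.random.default_rng(0)
        rs, preds = [], []
        for _ in range(20):
            s = rng.uniform(-20, 80, 100)
            noise_sd = 15.0
            a = s + rng.normal(0, noise_sd, 100)
            b = s + rng.normal(0, noise_sd, 100)
            res = suppression_consistency(_consistency_table(a, b), "New1", "New2")
            rs.append(res.r)
            preds.append(np.var(s) / (np.var(s) + noise_sd**2))
        assert abs(np.mean(rs) - np.mean(preds)) < 0.1

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(1)
        rs = [
            suppression_consistency(
                _consistency_table(rng.uniform(-80, 20, 60), rng.uniform(-80, 20, 60)),
                "New1",
                "New2",
            ).r
            for _ in range(10)
        ]
        assert abs(np.mean(rs)) < 0.15

    def test_pipeline_consistency_matches_attenuation(self):
        out = consistency_experiment(shared=True, n_seeds=3, n_cells=15, seed=2)
        assert out["mean_r"] > 0.8
        assert abs(out["mean_r"] - out["mean_attenuation_prediction"]) < 0.1

    def test_insufficient_shared_cells_raises(self):
        t = _consistency_table([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            suppression_consistency(t, "New1", "New2")


class TestStratification:
    def _multi_day(self, values_by_day):
        rows = []
        for d, vals in enumerate(values_by_day, start=1):
            for c, v in enumerate(vals):
                rows.append(
                    {"cell": c, "mouse": "A", "day": d, "context": "New1", "percent_change": v}
                )
        return pd.DataFrame(rows)

    def test_persistent_ordering_means_never_cross(self):
        base = np.linspace(-80, 0, 16)
        days = [base, base * 0.7, base * 0.5, base * 0.3]
        per_stratum, _ = stratify_by_initial_suppression(self._multi_day(days))
        arr = per_stratum.to_numpy()
        for d in range(arr.shape[0]):
            assert np.all(np.diff(arr[d]) > 0)  # stratum 0 stays most suppressed

    def test_identical_cells_give_equal_strata(self):
        days = [np.zeros(8), np.zeros(8)]
        per_stratum, _ = stratify_by_initial_suppression(self._multi_day(days))
        assert np.allclose(per_stratum.to_numpy(), 0.0)

    def test_quantiles_partition_cells_exactly_once(self):
        rng = np.random.default_rng(0)
        days = [rng.normal(-40, 20, 21)]
        _, assignment = stratify_by_initial_suppression(self._multi_day(days))
        assert len(assignment) == 21
        assert set(assignment.values()) <= {0, 1, 2, 3}

    def test_fewer_cells_than_strata_raises(self):
        with pytest.raises(ValueError):
            stratify_by_initial_suppression(self._multi_day([[1.0, 2.0]]), n_strata=4)


class TestDistance:
    def test_location_independent_suppression_uncorrelated(self):
        rng = np.random.default_rng(0)
        cent = rng.uniform(0, 500, (60, 2))
        pc = rng.uniform(-80, 20, 60)
        dff = rng.normal(0, 1, (60, 400))
        out = distance_analyses(cent, pc, dff)
        assert abs(out["r_dist_dsupp"]) < 0.1 and not out["degenerate"]

    def test_distance_dependent_activity_similarity(self):
        rng = np.random.default_rng(1)
        n = 40
        cent = rng.uniform(0, 200, (n, 2))
        # cells share a latent with weights decaying in distance from a focus
        latent = rng.normal(0, 1, 600)
        w = np.exp(-np.hypot(cent[:, 0] - 100, cent[:, 1] - 100) / 60.0)
        dff = np.outer(w, latent) + 0.5 * rng.normal(0, 1, (n, 600))
        out = distance_analyses(cent, np.zeros(n) + rng.normal(0, 1, n), dff)
        assert out["r_dist_actcorr"] < 0.0

    def test_coincident_centroids_degenerate(self):
        cent = np.zeros((5, 2))
        out = distance_analyses(cent, np.arange(5.0), np.random.default_rng(2).normal(0, 1, (5, 50)))
        assert out["degenerate"]


class TestPhaseClassification:
    def _stop_setup(self, coupling=+1.0, shift=0):
        rng = np.random.default_rng(0)
        fr = 10.0
        n = 6000
        speed = np.zeros(n)
        stops = np.arange(300, n - 300, 400)
        for s in stops:
            speed[s - 200 : s] = 20.0  # running then stopping at s
        act = coupling * speed / 20.0 + 0.01 * rng.normal(0, 1, n)
        if shift:
            act = np.roll(act, shift)
        return act, speed, stops, fr

    def test_locomotion_coupled_cell(self):
        act, speed, stops, fr = self._stop_setup(+1.0)
        label, phase = classify_locomotion_phase(act, speed, stops, fr)
        assert label == "locomotion" and abs(phase) < np.pi / 4

    def test_immobility_coupled_cell(self):
        act, speed, stops, fr = self._stop_setup(-1.0)
        label, phase = classify_locomotion_phase(act, speed, stops, fr)
        assert label == "immobility" and abs(abs(phase) - np.pi) < np.pi / 4

    def test_too_few_stops_raises(self):
        act, speed, stops, fr = self._stop_setup()
        with pytest.raises(ValueError, match="stop events"):
            classify_locomotion_phase(act, speed, stops[:2], fr)

    def test_flat_activity_raises(self):
        act, speed, stops, fr = self._stop_setup()
        with pytest.raises(ValueError, match="flat"):
            classify_locomotion_phase(np.zeros_like(act), speed, stops, fr)

    def test_detect_stops_finds_run_to_rest_transitions(self):
        speed = np.zeros(500)
        speed[50:150] = 20.0
        speed[300:420] = 20.0
        stops = detect_stops(speed, frame_rate=10.0)
        assert list(stops) == [150, 420]

    def test_stop_triggered_average_window(self):
        x = np.arange(100.0)
        avg = stop_triggered_average(x, np.array([50]), 5)
        assert np.allclose(avg, np.arange(45.0, 56.0))


class TestSpatialMap:
    def test_uniform_activity_flat_map(self):
        pos = np.linspace(0, 179.9, 900)
        v = np.full(900, 10.0)
        m = spatial_activity_map(np.full(900, 0.5), pos, v)
        assert np.allclose(m[0][np.isfinite(m[0])], 0.5)
        assert np.all(np.isnan(m[1]))  # never runs in the negative direction

    def test_indicator_activity_peaks_in_own_bin(self):
        pos = np.linspace(0, 179.9, 900)
        v = np.full(900, 10.0)
        y = ((pos >= 60) & (pos < 80)).astype(float)
        m = spatial_activity_map(y, pos, v)[0]
        assert m[3] == pytest.approx(1.0)
        others = np.delete(m, 3)
        assert np.nanmax(np.abs(others[np.isfinite(others)])) < 0.5

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 180, 2000)
        v = rng.choice([-10.0, 10.0], 2000)
        y = rng.normal(0, 1, 2000)
        m = spatial_activity_map(y, pos, v)
        idx = np.minimum((pos / 20).astype(int), 8)
        for row, mask in ((0, v > 1.0), (1, v < -1.0)):
            for b in range(9):
                sel = mask & (idx == b)
                if sel.sum() >= 2:
                    assert m[row, b] == pytest.approx(y[sel].mean())
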