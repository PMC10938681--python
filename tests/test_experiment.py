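"""Replicate protocol, malignancy classification, sweep aggregation."""

import numpy as np
import pandas as pd
import pytest

from patchytissue.energy import MechanicalParams
from patchytissue.experiment import (RunRecord, SimulationConfig,
                                     aggregate_records, classify_malignant,
                                     run_replicate, scenario_grid, sweep)


def tiny_config(**overrides):
    kw = dict(box_edge=40.0, n_cells=64, max_iterations=1500,
              cycle_max_iterations=500, window=250, n_cycles=2,
              patchiness_windows=(20.0,), mech=MechanicalParams())
    kw.update(overrides)
    return SimulationConfig(**kw)


def fake_record(scenario, seed, delta, c, mode=465.0, n_seeds=0):
    config = tiny_config(stiffness_mode=mode, n_seed_clusters=n_seeds)
    baseline = 500.0
    cycles = pd.DataFrame({
        "cycle": [0, 1], "n_cells": [64, 64],
        "mean_stiffness_pa": [baseline, baseline + delta],
        "n_tumor_like": [3, 4], "n_stiff": [61, 60],
    })
    rec = RunRecord(scenario=scenario, seed=seed, config=config,
                    initial_patchiness={20.0: c}, cycles=cycles,
                    baseline_mean_stiffness=baseline,
                    final_mean_stiffness=baseline + delta)
    rec.malignant = classify_malignant(rec, 15.0)
    return rec


class TestClassifyMalignant:
    @pytest.mark.parametrize("delta,expected", [
        (-20.0, True),    # clear drop
        (-15.0, True),    # boundary inclusive
        (-14.9, False),   # just under
        (0.0, False),
        (+15.0, False),   # rare stiffening: recorded, never malignant
    ])
    def test_threshold(self, delta, expected):
        rec = fake_record("s", 0, delta, 0.8)
        assert classify_malignant(rec, 15.0) is expected


class TestRunReplicate:
    def test_frozen_fate_means_no_change(self):
        # p0 -> 0: no deaths or divisions, stiffness multiset static
        cfg = tiny_config(mech=MechanicalParams(p0=1e-9))
        rec = run_replicate(cfg, seed=5)
        assert rec.delta_mean_stiffness == pytest.approx(0.0, abs=1e-12)
        assert not rec.malignant
        assert (rec.cycles["n_cells"] == 64).all()

    def test_snapshots_written_per_cycle(self, tmp_path):
        from patchytissue.io import read_points
        cfg = tiny_config(n_cycles=1, mech=MechanicalParams(p0=1e-9))
        run_replicate(cfg, seed=5, snapshot_dir=tmp_path)
        files = sorted(p.name for p in tmp_path.glob("cycle_*.csv"))
        assert files == ["cycle_00.csv", "cycle_01.csv"]
        pos, stiff = read_points(tmp_path / "cycle_01.csv")
        assert pos.shape == (64, 3)
        assert len(stiff) == 64

    def test_deterministic_for_fixed_seed(self):
        cfg = tiny_config()
        r1 = run_replicate(cfg, seed=9)
        r2 = run_replicate(cfg, seed=9)
        pd.testing.assert_frame_equal(r1.cycles, r2.cycles)
        assert r1.initial_patchiness == r2.initial_patchiness
        assert r1.delta_mean_stiffness == r2.delta_mean_stiffness

    def test_counts_partition_population(self):
        cfg = tiny_config(n_cycles=3)
        rec = run_replicate(cfg, seed=3)
        assert (rec.cycles["n_tumor_like"] + rec.cycles["n_stiff"]
                == rec.cycles["n_cells"]).all()
        assert len(rec.cycles) == 4  # cycle 0 + 3 fate cycles

    def test_tumor_threshold_default_is_20pct_below_mean(self):
        assert tiny_config().tumor_threshold_pa == pytest.approx(400.0)
        assert tiny_config(stiffness_mean=600.0).tumor_threshold_pa == \
            pytest.approx(480.0)
        assert tiny_config(tumor_threshold=390.0).tumor_threshold_pa == 390.0


class TestAggregation:
    def make_records(self):
        # two scenarios with hand-constructed deltas and c values
        recs = [
            fake_record("mode465_mixed", 1, -2.0, 0.70),
            fake_record("mode465_mixed", 2, +1.0, 0.72),
            fake_record("mode465_mixed", 3, -16.0, 0.74),
            fake_record("mode425_seeds8", 4, -18.0, 0.91, 425.0, 8),
            fake_record("mode425_seeds8", 5, -22.0, 0.93, 425.0, 8),
            fake_record("mode425_seeds8", 6, -10.0, 0.92, 425.0, 8),
        ]
        configs = [recs[0].config, recs[3].config]
        return recs, configs

    def test_transformation_probabilities(self):
        recs, configs = self.make_records()
        s = aggregate_records(recs, configs, patchiness_window=20.0)
        by = s.scenarios.set_index("scenario")
        assert by.loc["mode465_mixed", "transformation_probability"] == \
            pytest.approx(1.0 / 3.0)
        assert by.loc["mode425_seeds8", "transformation_probability"] == \
            pytest.approx(2.0 / 3.0)

    def test_t_statistics_match_textbook_formula(self):
        recs, configs = self.make_records()
        s = aggregate_records(recs, configs, patchiness_window=20.0,
                              c_bin_width=0.05)
        # the bin [0.90, 0.95) holds exactly the three clustered deltas
        bins = s.patchiness_bins
        row = bins.iloc[int(np.argmin(np.abs(bins["c_bin_left"] - 0.90)))]
        d = np.array([-18.0, -22.0, -10.0])
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert row["n"] == 3
        assert row["mean_delta_stiffness_pa"] == pytest.approx(d.mean())
        assert row["t_statistic"] == pytest.approx(t_hand, rel=1e-12)
        # two-sided p from the t distribution with n-1 dof
        from scipy.stats import t as tdist
        p_hand = 2 * tdist.sf(abs(t_hand), len(d) - 1)
        assert row["p_value"] == pytest.approx(p_hand, rel=1e-12)

    def test_replicate_order_invariance(self):
        recs, configs = self.make_records()
        s1 = aggregate_records(recs, configs, patchiness_window=20.0)
        rng = np.random.default_rng(0)
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        s2 = aggregate_records(shuffled, configs, patchiness_window=20.0)
        pd.testing.assert_frame_equal(s1.scenarios, s2.scenarios)
        pd.testing.assert_frame_equal(s1.patchiness_bins, s2.patchiness_bins)

    def test_all_benign_gives_zero_probability(self):
        recs = [fake_record("mode465_mixed", i, -1.0, 0.7) for i in range(4)]
        s = aggregate_records(recs, [recs[0].config], patchiness_window=20.0)
        assert (s.scenarios["transformation_probability"] == 0).all()

    def test_rank_correlations_sign(self):
        recs, configs = self.make_records()
        s = aggregate_records(recs, configs, patchiness_window=20.0)
        rc = s.rank_correlations()
        # higher variance & clustering scenario has the higher probability
        assert rc["variance"]["spearman_rho"] > 0
        assert rc["clustering"]["spearman_rho"] > 0


class TestScenarioGrid:
    def test_grid_crosses_modes_and_clustering(self):
        configs = scenario_grid([465.0, 425.0], [0, 8], base=tiny_config())
        assert len(configs) == 4
        names = {c.scenario for c in configs}
        assert names == {"mode465_mixed", "mode465_seeds8",
                         "mode425_mixed", "mode425_seeds8"}
        # base settings survive the grid
        assert all(c.n_cells == 64 for c in configs)
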