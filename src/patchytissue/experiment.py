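"""Experiment driver: replicates, malignancy classification, scenario sweeps.

One replicate runs the full protocol — seed an initial tissue, relax it to its
energetic steady state, then alternate synchronous death/division sweeps with
re-relaxation for a fixed number of fate cycles — while tracking the mean cell
stiffness and the tumor-like (soft) cell count.  A drop of the tissue's mean
stiffness by 15 Pa over the run classifies the replicate as a malignant
transformation; cells below 400 Pa (20 % under the healthy 500 Pa mean) are
counted as tumor-like.

A sweep runs replicate ensembles over scenarios (stiffness-distribution mode ×
clustering level), estimates the transformation probability per scenario, and
relates each replicate's initial patchiness index to its stiffness change
(one-sample t-tests per patchiness bin).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import relax
from .energy import MechanicalParams
from .fate import FateContext, apply_fates, decide_fates
from .geometry import Box
from .patchiness import patchiness_index
from .seeding import (ClusteringSpec, StiffnessDistributionSpec,
                      seed_clustered, seed_homogeneous)
from .state import TissueState

__all__ = [
    "SimulationConfig",
    "aggregate_records",
    "RunRecord",
    "SweepSummary",
    "run_replicate",
    "classify_malignant",
    "sweep",
    "scenario_grid",
    "paper_config",
    "desk_config",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one replicate.

    The defaults reproduce the full-scale protocol: 512 cells in an 80 µm
    periodic box (mean cell volume 1000 µm³), up to 70,000 Metropolis
    iterations per relaxation (7 cells moved 0.5 µm-exponential steps per
    proposal, 1000-iteration energy averaging), 20 fate cycles, ±5 % daughter
    stiffness inheritance, 400 Pa tumor-like threshold and 15 Pa malignancy
    drop.
    """

    box_edge: float = 80.0
    n_cells: int = 512
    stiffness_mean: float = 500.0
    stiffness_mode: float = 465.0
    n_seed_clusters: int = 0          # 0 = well-mixed control
    placement_radius: float = 10.0
    mech: MechanicalParams = field(default_factory=MechanicalParams)
    max_iterations: int = 70_000      # initial relaxation budget
    cycle_max_iterations: int | None = None   # per-cycle budget (None = same)
    window: int = 1000
    tolerance: float = 1e-3
    cells_per_move: int = 7
    mean_step: float = 0.5
    n_cycles: int = 20
    tumor_threshold: float | None = None      # None = 80 % of the healthy mean
    malignant_drop: float = 15.0
    patchiness_windows: tuple = (40.0,)
    patchiness_stride: float = 10.0
    patchiness_bin: float = 10.0

    @property
    def tumor_threshold_pa(self) -> float:
        """Tumor-like boundary: cells >= 20 % softer than the healthy mean."""
        if self.tumor_threshold is not None:
            return self.tumor_threshold
        return 0.8 * self.stiffness_mean

    @property
    def scenario(self) -> str:
        cl = f"seeds{self.n_seed_clusters}" if self.n_seed_clusters else "mixed"
        return f"mode{self.stiffness_mode:g}_{cl}"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["patchiness_windows"] = list(self.patchiness_windows)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "mech" in d and isinstance(d["mech"], dict):
            d["mech"] = MechanicalParams(**d["mech"])
        if "patchiness_windows" in d:
            d["patchiness_windows"] = tuple(d["patchiness_windows"])
        return cls(**d)


def paper_config(mode: float = 465.0, n_seed_clusters: int = 0,
                 **overrides) -> SimulationConfig:
    """Full-scale protocol configuration."""
    return SimulationConfig(stiffness_mode=mode,
                            n_seed_clusters=n_seed_clusters, **overrides)


def desk_config(mode: float = 465.0, n_seed_clusters: int = 0,
                **overrides) -> SimulationConfig:
    """Reduced configuration for desk-scale ensembles.

    128 cells at the same density (box ≈ 50.4 µm), shorter relaxation budgets
    and 10 fate cycles; the 40 µm patchiness window is retained.
    """
    kw = dict(
        box_edge=(128 * 1000.0) ** (1.0 / 3.0),
        n_cells=128,
        max_iterations=10_000,
        cycle_max_iterations=2_500,
        window=500,
        n_cycles=10,
        stiffness_mode=mode,
        n_seed_clusters=n_seed_clusters,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class RunRecord:
    """Per-cycle summaries and final classification of one replicate."""

    scenario: str
    seed: int
    config: SimulationConfig
    initial_patchiness: dict          # window edge (µm) -> c
    cycles: pd.DataFrame              # cycle, n_cells, mean_stiffness_pa, n_tumor_like, n_stiff
    baseline_mean_stiffness: float    # after seeding == after initial relaxation
    final_mean_stiffness: float
    malignant: bool = False

    @property
    def delta_mean_stiffness(self) -> float:
        return self.final_mean_stiffness - self.baseline_mean_stiffness

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "initial_patchiness": {str(k): v
                                   for k, v in self.initial_patchiness.items()},
            "cycles": self.cycles.to_dict(orient="list"),
            "baseline_mean_stiffness": self.baseline_mean_stiffness,
            "final_mean_stiffness": self.final_mean_stiffness,
            "delta_mean_stiffness": self.delta_mean_stiffness,
            "malignant": bool(self.malignant),
        }


def classify_malignant(record: RunRecord, threshold_drop: float = 15.0) -> bool:
    """Malignant iff the mean stiffness dropped by at least ``threshold_drop``.

    The rare stiffening case (mean increases) is recorded but never malignant.
    """
    return (record.baseline_mean_stiffness
            - record.final_mean_stiffness) >= threshold_drop


def _cycle_row(state: TissueState, cycle: int, threshold: float) -> dict:
    n_tumor = int((state.stiffness < threshold).sum())
    return {
        "cycle": cycle,
        "n_cells": state.n_cells,
        "mean_stiffness_pa": state.mean_stiffness(),
        "n_tumor_like": n_tumor,
        "n_stiff": state.n_cells - n_tumor,
    }


def build_initial_tissue(config: SimulationConfig, rng) -> TissueState:
    """Seed a tissue per the configured clustering level (unrelaxed)."""
    box = Box(config.box_edge)
    dist = StiffnessDistributionSpec(config.stiffness_mean,
                                     config.stiffness_mode)
    if config.n_seed_clusters > 0:
        spec = ClusteringSpec(n_seeds=config.n_seed_clusters,
                              placement_radius=config.placement_radius)
        return seed_clustered(config.n_cells, box, dist, spec, rng,
                              config.mech)
    return seed_homogeneous(config.n_cells, box, dist, rng, config.mech)


def run_replicate(config: SimulationConfig, seed: int,
                  snapshot_dir=None) -> RunRecord:
    """Run one full replicate: seed → relax → n_cycles × (fate → relax).

    Deterministic for a fixed (config, seed).  With ``snapshot_dir`` set, the
    relaxed point configuration of every cycle is written there as the
    standard point CSV (``cycle_00.csv`` ...).
    """
    def snapshot(state, cycle):
        if snapshot_dir is not None:
            from pathlib import Path

            from .io import write_points
            out = Path(snapshot_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_points(out / f"cycle_{cycle:02d}.csv", state)

    rng = np.random.default_rng(seed)
    state = build_initial_tissue(config, rng)
    state, _ = relax(state, config.max_iterations, config.window,
                     config.tolerance, config.cells_per_move,
                     config.mean_step, rng)

    initial_patchiness = {
        w: patchiness_index(state, w, config.patchiness_stride,
                            config.patchiness_bin).patchiness_index
        for w in config.patchiness_windows
    }
    ctx = FateContext.from_state(state)
    threshold = config.tumor_threshold_pa
    baseline = state.mean_stiffness()
    rows = [_cycle_row(state, 0, threshold)]
    snapshot(state, 0)

    cycle_budget = (config.cycle_max_iterations
                    if config.cycle_max_iterations is not None
                    else config.max_iterations)
    for cycle in range(1, config.n_cycles + 1):
        outcome = decide_fates(state, ctx, rng)
        state = apply_fates(state, outcome, rng)
        state, _ = relax(state, cycle_budget, config.window,
                         config.tolerance, config.cells_per_move,
                         config.mean_step, rng)
        rows.append(_cycle_row(state, cycle, threshold))
        snapshot(state, cycle)

    record = RunRecord(
        scenario=config.scenario,
        seed=seed,
        config=config,
        initial_patchiness=initial_patchiness,
        cycles=pd.DataFrame(rows),
        baseline_mean_stiffness=baseline,
        final_mean_stiffness=state.mean_stiffness(),
    )
    record.malignant = classify_malignant(record, config.malignant_drop)
    return record


def scenario_grid(modes, seed_counts, base: SimulationConfig | None = None,
                  factory=None) -> list[SimulationConfig]:
    """Cross stiffness-distribution modes with clustering levels.

    ``seed_counts`` uses 0 for the well-mixed control; lower modes mean higher
    variance, fewer seeds mean larger clusters.
    """
    if factory is None:
        factory = paper_config if base is None else (
            lambda m, s: dataclasses.replace(base, stiffness_mode=m,
                                             n_seed_clusters=s))
    return [factory(m, s) for m in modes for s in seed_counts]


@dataclass
class SweepSummary:
    """Aggregated results of a scenario sweep."""

    scenarios: pd.DataFrame        # per scenario: transformation probability etc.
    patchiness_bins: pd.DataFrame  # per c bin: mean Δ stiffness, SE, t-test p
    records: list
    failures: list = field(default_factory=list)  # aborted replicates

    def rank_correlations(self) -> dict:
        """Spearman rank correlation of transformation probability with
        distribution variance (lower mode = higher) and clustering level
        (fewer seeds = stronger; the mixed control ranks lowest)."""
        df = self.scenarios
        variance_rank = -df["stiffness_mode"]
        # clustering strength: 0 for mixed, else decreasing in seed count
        clustering_rank = np.where(df["n_seed_clusters"] == 0, 0.0,
                                   1.0 / df["n_seed_clusters"])
        out = {}
        for name, x in [("variance", variance_rank),
                        ("clustering", clustering_rank)]:
            if len(set(np.asarray(x))) > 1:
                rho, p = stats.spearmanr(x, df["transformation_probability"])
            else:
                rho, p = np.nan, np.nan
            out[name] = {"spearman_rho": float(rho), "p_value": float(p)}
        return out


def sweep(configs, n_replicates: int = 10, base_seed: int = 0,
          patchiness_window: float | None = None,
          c_bin_width: float = 0.05) -> SweepSummary:
    """Run an ensemble of replicates per scenario and aggregate.

    Replicate seeds derive deterministically from ``base_seed``; the whole
    sweep is a pure function of (configs, n_replicates, base_seed).  The
    patchiness-vs-outcome table pools every replicate, bins the initial
    patchiness index (width ``c_bin_width``) and runs a two-sided one-sample
    t-test of mean Δ stiffness == 0 per bin (no multiple-testing correction,
    raw p-values).
    """
    configs = list(configs)
    if n_replicates < 1:
        raise ValueError("need at least one replicate per scenario")
    ss = np.random.SeedSequence(base_seed)
    seeds = (ss.generate_state(len(configs) * n_replicates)
             & 0x7FFFFFFF).reshape(len(configs), n_replicates)

    records = []
    failures = []
    for ci, config in enumerate(configs):
        for ri in range(n_replicates):
            seed = int(seeds[ci, ri])
            try:
                rec = run_replicate(config, seed)
            except Exception as exc:   # a module error aborts the replicate only
                failures.append({"scenario": config.scenario, "seed": seed,
                                 "error": f"{type(exc).__name__}: {exc}"})
                log.error("scenario %s seed %d aborted: %s",
                          config.scenario, seed, exc)
                continue
            records.append(rec)
            log.info("scenario %s replicate %d: Δ = %+.1f Pa%s",
                     config.scenario, ri, rec.delta_mean_stiffness,
                     " (malignant)" if rec.malignant else "")
    summary = aggregate_records(records, configs, patchiness_window,
                                c_bin_width)
    summary.failures = failures
    return summary


def aggregate_records(records, configs, patchiness_window: float | None = None,
                      c_bin_width: float = 0.05) -> SweepSummary:
    """Aggregate RunRecords into the per-scenario and per-patchiness-bin tables."""
    rows = []
    for config in configs:
        recs = [r for r in records if r.scenario == config.scenario]
        if not recs:
            rows.append({
                "scenario": config.scenario,
                "stiffness_mode": config.stiffness_mode,
                "n_seed_clusters": config.n_seed_clusters,
                "n_replicates": 0, "n_malignant": 0,
                "transformation_probability": np.nan,
                "mean_delta_stiffness_pa": np.nan,
                "se_delta_stiffness_pa": np.nan,
            })
            continue
        deltas = np.array([r.delta_mean_stiffness for r in recs])
        n_mal = sum(r.malignant for r in recs)
        rows.append({
            "scenario": config.scenario,
            "stiffness_mode": config.stiffness_mode,
            "n_seed_clusters": config.n_seed_clusters,
            "n_replicates": len(recs),
            "n_malignant": n_mal,
            "transformation_probability": n_mal / len(recs),
            "mean_delta_stiffness_pa": deltas.mean(),
            "se_delta_stiffness_pa": (deltas.std(ddof=1) / np.sqrt(len(deltas))
                                      if len(deltas) > 1 else np.nan),
        })
    scenarios = pd.DataFrame(rows)

    if patchiness_window is None:
        patchiness_window = configs[0].patchiness_windows[0]
    c_vals = np.array([r.initial_patchiness[patchiness_window]
                       for r in records])
    deltas = np.array([r.delta_mean_stiffness for r in records])
    finite = np.isfinite(c_vals)
    bin_rows = []
    if finite.any():
        lo = np.floor(c_vals[finite].min() / c_bin_width) * c_bin_width
        hi = c_vals[finite].max()
        edges = np.arange(lo, hi + c_bin_width, c_bin_width)
        for k in range(len(edges)):
            left = edges[k]
            right = left + c_bin_width
            mask = finite & (c_vals >= left) & (c_vals < right)
            if not mask.any():
                continue
            d = deltas[mask]
            if len(d) > 1:
                t, p = stats.ttest_1samp(d, 0.0)
            else:
                t, p = np.nan, np.nan
            bin_rows.append({
                "c_bin_left": left,
                "c_bin_right": right,
                "n": int(mask.sum()),
                "mean_delta_stiffness_pa": d.mean(),
                "se_delta_stiffness_pa": (d.std(ddof=1) / np.sqrt(len(d))
                                          if len(d) > 1 else np.nan),
                "t_statistic": float(t),
                "p_value": float(p),
            })
    patchiness_bins = pd.DataFrame(bin_rows)
    return SweepSummary(scenarios=scenarios, patchiness_bins=patchiness_bins,
                        records=records)
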