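"""File formats: point tables, configs, run outputs.

The standard point table is a CSV with header ``cell_id,x,y,z,stiffness_pa``
(positions in µm, stiffness in Pa).  Configs are YAML mirrors of
:class:`~patchytissue.experiment.SimulationConfig`; every output embeds the
full config for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import RelaxationTrace
from .experiment import RunRecord, SimulationConfig, SweepSummary
from .state import TissueState

__all__ = [
    "append_fate_events",
    "read_points",
    "save_tissue",
    "write_points",
    "write_windows",
    "load_config",
    "save_config",
    "save_run",
    "save_sweep",
    "write_trace",
]

POINT_COLUMNS = ["cell_id", "x", "y", "z", "stiffness_pa"]


def read_points(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a point table; returns (positions (n,3) µm, stiffness (n,) Pa)."""
    df = pd.read_csv(path)
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} "
                         f"(expected header {','.join(POINT_COLUMNS)})")
    df = df.sort_values("cell_id")
    return (df[["x", "y", "z"]].to_numpy(float),
            df["stiffness_pa"].to_numpy(float))


def write_points(path, state_or_arrays) -> None:
    """Write a point table from a TissueState or (positions, stiffness)."""
    if isinstance(state_or_arrays, TissueState):
        pos, stiff = state_or_arrays.positions, state_or_arrays.stiffness
    else:
        pos, stiff = state_or_arrays
    df = pd.DataFrame({
        "cell_id": np.arange(len(stiff)),
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "stiffness_pa": stiff,
    })
    df.to_csv(path, index=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimulationConfig.from_dict(data or {})


def save_config(path, config: SimulationConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_trace(path, trace: RelaxationTrace) -> None:
    pd.DataFrame({
        "iteration": trace.iterations,
        "window_mean_energy": trace.window_mean_energy,
        "acceptance_fraction": trace.acceptance_fraction,
    }).to_csv(path, index=False)


def save_tissue(out_dir, state: TissueState, name: str = "tissue",
                meta: dict | None = None) -> Path:
    """Write a tissue snapshot: point CSV plus a JSON sidecar with metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_points(out / f"{name}.csv", state)
    sidecar = {
        "n_cells": state.n_cells,
        "box_edge_um": state.box.edge_length,
        "mech": {
            "adhesion_energy_density": state.params.adhesion_energy_density,
            "lambda_osmotic": state.params.lambda_osmotic,
            "kbt_eff": state.params.kbt_eff,
            "p0": state.params.p0,
        },
        "relaxed": bool(state.relaxed),
    }
    if meta:
        sidecar.update(meta)
    with open(out / f"{name}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return out


def append_fate_events(path, cycle: int, state: TissueState, outcome,
                       daughters: list | None = None) -> None:
    """Append one cycle's fate events to a CSV log.

    Columns: ``cycle,cell_id,event,parent_stiffness,daughter_stiffness``
    (daughter stiffness empty for deaths; one row per daughter for divisions
    when ``daughters`` — a list of (parent id, stiffness) pairs — is given).
    """
    path = Path(path)
    rows = []
    for i in outcome.dying:
        rows.append((cycle, int(i), "die", state.stiffness[i], ""))
    if daughters:
        for parent, stiff in daughters:
            rows.append((cycle, int(parent), "divide",
                         state.stiffness[parent], stiff))
    else:
        for i in outcome.dividing:
            rows.append((cycle, int(i), "divide", state.stiffness[i], ""))
    new = not path.exists()
    with open(path, "a") as fh:
        if new:
            fh.write("cycle,cell_id,event,parent_stiffness,daughter_stiffness\n")
        for r in rows:
            fh.write(",".join(str(x) for x in r) + "\n")


def write_windows(path, result) -> None:
    """Per-window CSV of a HeterogeneityResult: origin, cell count, entropy."""
    pd.DataFrame({
        "x0": result.window_origins[:, 0],
        "y0": result.window_origins[:, 1],
        "z0": result.window_origins[:, 2],
        "n_cells": result.window_counts,
        "local_heterogeneity": result.local_heterogeneities,
    }).to_csv(path, index=False)


def save_run(out_dir, record: RunRecord) -> Path:
    """Write run_record.json and cycles.csv for one replicate."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_record.json", "w") as fh:
        json.dump(record.to_dict(), fh, indent=2, default=float)
    record.cycles.to_csv(out / "cycles.csv", index=False)
    return out


def save_sweep(out_dir, summary: SweepSummary) -> Path:
    """Write sweep_summary.csv, patchiness_bins.csv and all run records."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.scenarios.to_csv(out / "sweep_summary.csv", index=False)
    summary.patchiness_bins.to_csv(out / "patchiness_bins.csv", index=False)
    with open(out / "records.json", "w") as fh:
        json.dump([r.to_dict() for r in summary.records], fh, indent=2,
                  default=float)
    with open(out / "rank_correlations.json", "w") as fh:
        json.dump(summary.rank_correlations(), fh, indent=2)
    return out
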