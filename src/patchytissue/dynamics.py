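"""Metropolis rearrangement dynamics.

Tissue configurations evolve by small random multi-cell displacements accepted
with the Metropolis rule at an effective temperature (k_BT)_eff: moves that
lower the total mechanical energy are always accepted, energy-raising moves
with probability exp(-ΔU / (k_BT)_eff).  Iterating to a steady windowed mean
energy relaxes the tissue to its low-energy packing.

Random-number stream order (one chunk = one averaging window): cell ids →
directions → step magnitudes → acceptance uniforms → collision-rescue jitter.
Runs with the same seed are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _clip
from .state import TissueState

__all__ = ["propose_move", "accept", "relax", "RelaxationTrace"]


def propose_move(state: TissueState, n_cells: int, mean_step: float, rng):
    """Propose displaced positions for ``n_cells`` distinct random cells.

    Each chosen cell is displaced along an independent isotropic direction by
    a magnitude drawn from an exponential distribution with mean
    ``mean_step`` (µm); positions wrap into the box.

    Returns ``(ids, new_positions)``.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    if n_cells > state.n_cells:
        raise ValueError(f"cannot move {n_cells} of {state.n_cells} cells")
    if not mean_step > 0:
        raise ValueError("mean_step must be > 0")
    ids = rng.choice(state.n_cells, size=n_cells, replace=False)
    dirs = rng.normal(size=(n_cells, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    mags = rng.exponential(mean_step, size=n_cells)
    newpos = (state.positions[ids] + dirs * mags[:, None]) % state.box.edge_length
    return ids, newpos


def accept(delta_U: float, kbt_eff: float, rng) -> bool:
    """Metropolis acceptance: downhill always, uphill with exp(-ΔU/kT)."""
    if not kbt_eff > 0:
        raise ValueError("kbt_eff must be > 0")
    if delta_U <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_U / kbt_eff))


@dataclass
class RelaxationTrace:
    """Windowed energy trace of one relaxation run.

    ``window_mean_energy[k]`` is the total tissue energy averaged over
    iterations ``[k·window, (k+1)·window)``; ``acceptance_fraction`` the
    fraction of proposals accepted in that window.
    """

    window: int
    iterations: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    window_mean_energy: np.ndarray = field(default_factory=lambda: np.empty(0))
    acceptance_fraction: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False

    def append(self, iteration: int, mean_energy: float, frac: float) -> None:
        self.iterations = np.append(self.iterations, iteration)
        self.window_mean_energy = np.append(self.window_mean_energy, mean_energy)
        self.acceptance_fraction = np.append(self.acceptance_fraction, frac)


def _draw_chunk(rng, n: int, window: int, m: int, mean_step: float):
    """Pre-draw one window of proposal randomness (documented stream order)."""
    base = np.tile(np.arange(n), (window, 1))
    ids = rng.permuted(base, axis=1)[:, :m].astype(np.int64)
    dirs = rng.normal(size=(window, m, 3))
    dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
    mags = rng.exponential(mean_step, size=(window, m))
    urand = rng.random(window)
    jitter = rng.normal(size=(window, m, 3))
    return np.ascontiguousarray(ids), np.ascontiguousarray(dirs), mags, urand, jitter


def relax(state: TissueState, max_iterations: int = 70_000, window: int = 1000,
          tolerance: float = 1e-3, cells_per_move: int = 7,
          mean_step: float = 0.5, rng=None) -> tuple[TissueState, RelaxationTrace]:
    """Relax the tissue to an energetic steady state (in place).

    Runs Metropolis iterations (``cells_per_move`` cells displaced jointly per
    proposal, accepted or rejected as a block on the summed energy change)
    until the relative change between successive windowed mean energies drops
    below ``tolerance`` or ``max_iterations`` is reached.  Returns the state
    (marked relaxed) and the full trace.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if state.stale:
        state.retessellate()
    m = min(cells_per_move, state.n_cells)
    n = state.n_cells
    trace = RelaxationTrace(window=window)
    prev_mean = None
    done = 0
    while done < max_iterations:
        this = min(window, max_iterations - done)
        ids, dirs, mags, urand, jitter = _draw_chunk(rng, n, this, m, mean_step)
        tot, esum, nacc, err = _clip.relax_chunk(
            state.positions, state.cortex_k, state.box.edge_length,
            state._R0, state.A0, state.V0,
            state.params.adhesion_energy_density,
            state.params.lambda_osmotic, state.params.kbt_eff,
            state.volumes, state.surface_areas, state._nbr, state._nbrn,
            state._nbra, state._dmax, state.energies, state._total_energy,
            ids, dirs, mags, urand, jitter)
        if err != _clip.OK:
            raise RuntimeError(f"relaxation geometry update failed (code {err})")
        state._total_energy = tot
        done += this
        mean = esum / this
        trace.append(done, mean, nacc / this)
        if prev_mean is not None:
            denom = max(abs(prev_mean), 1e-12)
            if abs(mean - prev_mean) / denom < tolerance:
                trace.converged = True
                break
        prev_mean = mean
    state.relaxed = True
    return state, trace
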