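"""Stretch-dependent stochastic cell death and division.

Cell fate is mechanosensitive: the in-tissue surface area ``A_i`` measures how
stretched a cell is relative to its sphere-equivalent area ``A_sp`` (a
perfectly round, compressed cell) and the homeostatic mean area ``A_m``.
Round cells die with high probability and almost never divide; stretched cells
divide readily and rarely die::

    p_death = p0 ** ((A_i - A_sp) / (A_m - A_sp))
    p_div   = (1 + (1-p0)/p0 * [(1-p0)/(100-p0)] ** ((A_i - A_m)/(A_m - A_sp)))^-1

At ``A_i = A_m`` both equal the baseline ``p0`` (homeostasis: death and
division balance); at ``A_i = A_sp`` death is certain (probability 1) and
division drops to exactly ``p0/100``.  The literal constant 100 is part of the
model.  Fate decisions are synchronous — all drawn from the same pre-fate
tessellation — and a dividing cell's daughters inherit its stiffness up to a
±5 % (max) uniform variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state import TissueState

__all__ = ["FateContext", "FateOutcome", "p_death", "p_div", "decide_fates",
           "apply_fates"]

#: daughters inherit parent stiffness times (1 + u), u ~ U(-this, +this)
DAUGHTER_STIFFNESS_VARIATION = 0.05

#: daughter points are placed at parent ± this offset (µm) along a random
#: coordinate axis; small enough that the subsequent relaxation, not the
#: placement, determines the local geometry
DAUGHTER_OFFSET_UM = 0.5

#: relative tolerance for clamping A_i marginally below A_sp (floating point)
_ASP_CLAMP_RTOL = 1e-9


def _validate_areas(A_i, A_sp, A_m):
    A_i = np.asarray(A_i, dtype=float)
    A_sp = np.asarray(A_sp, dtype=float)
    if np.any(A_m <= A_sp):
        raise ValueError("A_m must exceed every A_sp (tessellated cells are "
                         "never perfectly spherical)")
    low = A_i < A_sp
    if np.any(low):
        if np.any(A_i < A_sp * (1.0 - _ASP_CLAMP_RTOL)):
            raise ValueError(
                "A_i < A_sp: a cell's area cannot be below its "
                "sphere-equivalent area")
        A_i = np.where(low, A_sp, A_i)
    return A_i, A_sp


def p_death(A_i, A_sp, A_m, p0):
    """Death probability of a cell with area ``A_i``; decreasing in ``A_i``."""
    A_i, A_sp = _validate_areas(A_i, A_sp, A_m)
    expo = (A_i - A_sp) / (A_m - A_sp)
    out = p0**expo
    return float(out) if out.ndim == 0 else out


def p_div(A_i, A_sp, A_m, p0):
    """Division probability of a cell with area ``A_i``; increasing in ``A_i``."""
    A_i, A_sp = _validate_areas(A_i, A_sp, A_m)
    expo = (A_i - A_m) / (A_m - A_sp)
    out = 1.0 / (1.0 + (1.0 - p0) / p0 * ((1.0 - p0) / (100.0 - p0))**expo)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FateContext:
    """Fate parameters: homeostatic mean area and baseline probability.

    ``A_m`` is measured once from the initial relaxed healthy tissue (mean of
    ``A_i``) and then frozen for the run; the probabilities of the evolving
    tissue are always referred to that baseline.
    """

    A_m: float
    p0: float

    def __post_init__(self):
        if not 0 < self.p0 < 0.5:
            raise ValueError(f"p0 must be in (0, 0.5), got {self.p0}")
        if not self.A_m > 0:
            raise ValueError("A_m must be > 0")

    @classmethod
    def from_state(cls, state: TissueState) -> "FateContext":
        return cls(A_m=float(state.surface_areas.mean()), p0=state.params.p0)


# per-cell decision codes
NONE, DIE, DIVIDE = 0, 1, 2


@dataclass
class FateOutcome:
    """Synchronous fate decisions for one cycle."""

    decisions: np.ndarray            # int8 codes per cell: 0 none, 1 die, 2 divide
    p_death: np.ndarray
    p_div: np.ndarray

    @property
    def dying(self) -> np.ndarray:
        return np.nonzero(self.decisions == DIE)[0]

    @property
    def dividing(self) -> np.ndarray:
        return np.nonzero(self.decisions == DIVIDE)[0]

    @property
    def n_events(self) -> int:
        return int((self.decisions != NONE).sum())


def decide_fates(state: TissueState, ctx: FateContext, rng) -> FateOutcome:
    """Draw one synchronous fate sweep from the current tessellation.

    Every cell independently dies with ``p_death``, divides with ``p_div``,
    or does neither with ``1 - (p_death + p_div)``; all probabilities are
    computed from the same pre-fate geometry.
    """
    if state.stale:
        raise RuntimeError("tessellation is stale; relax or retessellate first")
    A_i = state.surface_areas
    A_sp = state.tessellation.sphere_equivalent_areas
    pd = p_death(A_i, A_sp, ctx.A_m, ctx.p0)
    pv = p_div(A_i, A_sp, ctx.A_m, ctx.p0)
    total = pd + pv
    if np.any(total > 1.0):
        i = int(np.argmax(total))
        raise ValueError(
            f"invalid parameterization: p_death + p_div = {total[i]:.4f} > 1 "
            f"for cell {i} (A_i = {A_i[i]:.1f} µm²)")
    u = rng.random(state.n_cells)
    decisions = np.full(state.n_cells, NONE, dtype=np.int8)
    decisions[u < pd] = DIE
    decisions[(u >= pd) & (u < total)] = DIVIDE
    return FateOutcome(decisions=decisions, p_death=pd, p_div=pv)


def apply_fates(state: TissueState, outcome: FateOutcome, rng) -> TissueState:
    """Apply a fate sweep: remove dying cells, split dividing ones.

    Daughters are placed at the parent position ± `DAUGHTER_OFFSET_UM` along a
    random coordinate axis (wrapped), each independently inheriting
    ``parent stiffness × (1 + u)`` with ``u ~ U(-0.05, +0.05)``.  Returns a
    fresh, retessellated state marked not relaxed.
    """
    if outcome.decisions.shape[0] != state.n_cells:
        raise ValueError("outcome does not match this state")
    L = state.box.edge_length
    keep = outcome.decisions != DIE
    positions = [state.positions[keep]]
    stiffness = [state.stiffness[keep]]
    # dividing cells are among the kept; replace each by two daughters
    for i in outcome.dividing:
        axis = rng.integers(3)
        offset = np.zeros(3)
        offset[axis] = DAUGHTER_OFFSET_UM
        p_plus = (state.positions[i] + offset) % L
        p_minus = (state.positions[i] - offset) % L
        var = rng.uniform(-DAUGHTER_STIFFNESS_VARIATION,
                          DAUGHTER_STIFFNESS_VARIATION, size=2)
        # the parent's slot (already in `keep`) becomes daughter one
        kept_index = int(keep[:i].sum())
        positions[0][kept_index] = p_plus
        stiffness[0][kept_index] = state.stiffness[i] * (1.0 + var[0])
        positions.append(p_minus[None, :])
        stiffness.append(np.array([state.stiffness[i] * (1.0 + var[1])]))
    pos = np.vstack(positions)
    stiff = np.concatenate(stiffness)
    if pos.shape[0] < 2:
        raise RuntimeError("fate sweep would leave fewer than 2 cells")
    # daughters of adjacent parents can land on top of each other; nudge apart
    from .geometry import DUPLICATE_TOL
    for _ in range(10):
        d = pos[:, None, :] - pos[None, :, :]
        d -= L * np.rint(d / L)
        d2 = np.einsum("ijk,ijk->ij", d, d)
        np.fill_diagonal(d2, np.inf)
        bad = np.unique(np.nonzero(d2 < DUPLICATE_TOL**2)[0])
        if bad.size == 0:
            break
        pos[bad] = (pos[bad] + rng.normal(scale=1e-3, size=(bad.size, 3))) % L
    new = TissueState(pos, stiff, state.box, state.params, V0=state.V0)
    new.relaxed = False
    return new
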