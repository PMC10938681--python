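"""Mutable tissue state: cells + box + cached tessellation and energies.

`TissueState` is the object the Monte-Carlo loop mutates.  It stores cell
positions and stiffness values as flat numpy arrays together with the cached
per-cell Voronoi geometry (volume, surface area, facet table) and per-cell
energy, so incremental moves only touch the affected rows.
"""

from __future__ import annotations

import numpy as np

from . import _clip
from .energy import (CORTEX_THICKNESS_UM, V0_DEFAULT, Cell, MechanicalParams)
from .geometry import (Box, Tessellation, check_points,
                       default_candidate_radius, sphere_equivalent_area,
                       tessellate_arrays)

__all__ = ["TissueState"]


class TissueState:
    """Cells, box, tessellation and cached energies of one tissue.

    Invariants maintained: the cached tessellation is consistent with the
    positions whenever ``stale`` is False, and ``total_energy`` equals the sum
    of the cached per-cell energies.
    """

    def __init__(self, positions, stiffness, box: Box,
                 params: MechanicalParams | None = None,
                 V0: float = V0_DEFAULT):
        self.box = box
        self.params = params if params is not None else MechanicalParams()
        self.positions = check_points(positions, box)
        self.stiffness = np.asarray(stiffness, dtype=float).copy()
        if self.stiffness.shape != (self.positions.shape[0],):
            raise ValueError("stiffness must be one value per cell")
        if np.any(self.stiffness <= 0):
            raise ValueError("all stiffness values must be > 0")
        self.V0 = float(V0)
        self.A0 = sphere_equivalent_area(self.V0)
        self.relaxed = False
        self.stale = True
        self.retessellate()

    # -- basic accessors ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def cortex_k(self) -> np.ndarray:
        """Per-cell areal cortex stiffness (Pa·µm)."""
        return self.stiffness * CORTEX_THICKNESS_UM

    @property
    def tessellation(self) -> Tessellation:
        if self.stale:
            raise RuntimeError("tessellation is stale; call retessellate()")
        return Tessellation(self.box, self.volumes, self.surface_areas,
                            self._nbr, self._nbrn, self._nbra, self._dmax)

    @property
    def total_energy(self) -> float:
        if self.stale:
            raise RuntimeError("tessellation is stale; call retessellate()")
        return self._total_energy

    def cell(self, i: int) -> Cell:
        return Cell(id=int(i), position=self.positions[i].copy(),
                    stiffness=float(self.stiffness[i]), V0=self.V0)

    def mean_stiffness(self) -> float:
        return float(self.stiffness.mean())

    # -- geometry / energy cache management --------------------------------

    def retessellate(self) -> None:
        """Full rebuild of the Voronoi geometry and per-cell energy caches."""
        (self.volumes, self.surface_areas, self._nbr, self._nbrn,
         self._nbra, self._dmax) = tessellate_arrays(
            self.positions, self.box.edge_length)
        self._R0 = default_candidate_radius(self.n_cells,
                                            self.box.edge_length)
        self.energies = np.empty(self.n_cells)
        self._total_energy = _clip.recompute_energies(
            self.cortex_k, self.volumes, self.surface_areas, self._nbra,
            self._nbrn, self.A0, self.V0,
            self.params.adhesion_energy_density,
            self.params.lambda_osmotic, self.energies)
        self._inA = np.zeros(self.n_cells, np.uint8)
        self.stale = False

    def _affected_buffers(self):
        """Scratch buffers for incremental move evaluation."""
        maxaff = _clip.MAXAFF
        return (np.empty(2 * maxaff + 1, np.int64),  # alist
                np.empty(maxaff),                     # tvol
                np.empty(maxaff),                     # tsarea
                np.empty((maxaff, _clip.MAXN), np.int64),
                np.empty(maxaff, np.int64),
                np.empty((maxaff, _clip.MAXN)),
                np.empty(maxaff),                     # tdmax
                np.empty(maxaff),                     # tU
                self._inA)

    def _clip_workspace(self):
        """Scratch buffers for the clipping kernels."""
        return (np.empty((2 * _clip.MAXF, _clip.MAXFV, 3)),
                np.empty(_clip.MAXF, np.int64),
                np.empty(_clip.MAXF, np.int64),
                np.empty(_clip.MAXCAND),
                np.empty((_clip.MAXF, _clip.MAXFV)),
                np.empty((4 * _clip.MAXFV, 3)),
                np.empty(_clip.MAXCAND),
                np.empty(_clip.MAXCAND),
                np.empty(_clip.MAXCAND),
                np.empty(_clip.MAXCAND),
                np.empty(_clip.MAXCAND, np.int64),
                np.empty(_clip.MAXCAND))

    def copy(self) -> "TissueState":
        new = TissueState.__new__(TissueState)
        new.box = self.box
        new.params = self.params
        new.positions = self.positions.copy()
        new.stiffness = self.stiffness.copy()
        new.V0 = self.V0
        new.A0 = self.A0
        new.relaxed = self.relaxed
        new.stale = self.stale
        new.volumes = self.volumes.copy()
        new.surface_areas = self.surface_areas.copy()
        new._nbr = self._nbr.copy()
        new._nbrn = self._nbrn.copy()
        new._nbra = self._nbra.copy()
        new._dmax = self._dmax.copy()
        new._R0 = self._R0
        new.energies = self.energies.copy()
        new._total_energy = self._total_energy
        new._inA = np.zeros(new.n_cells, np.uint8)
        return new
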