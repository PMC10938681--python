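"""Per-cell mechanical energy of point-cells in a dense tissue.

Each cell is a viscoelastic shell — an actin cortex around a liquid core —
whose energy has three terms::

    U_i = 1/2 k (A_i - A_0)^2 / A_0  -  1/2 Σ_j A_j γσ  -  λ ln(V_i / V_0)

* stretch: elastic cost of deforming the cortex away from its free-solution
  spherical area ``A_0`` (``k`` is the cortex areal stiffness);
* adhesion: energy released by intercellular bonds over each shared facet
  ``A_j`` (``γσ`` is bond energy × bond density, one uniform constant per
  pair); the 1/2 prefactor corrects double counting when per-cell energies are
  summed over the tissue, so each interface contributes ``A_j γσ`` once;
* osmotic: work done by the internal osmotic pressure in changing the volume
  from the free-solution ``V_0`` (``λ = P_0 V_0``).

Energies are expressed in Pa·µm³ (= 1e-18 J), native to the µm/Pa
parameterization of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CellGeometry, sphere_equivalent_area

__all__ = [
    "MechanicalParams",
    "Cell",
    "cell_energy",
    "tissue_energy",
    "delta_energy",
    "V0_DEFAULT",
    "CORTEX_THICKNESS_UM",
]

#: free-solution cell volume, µm³; identical for all cells (heterogeneity
#: enters through the cortex stiffness only)
V0_DEFAULT = 1000.0

#: actin cortex thickness used to map the measured elastic modulus (Pa) to an
#: areal cortex stiffness k (Pa·µm); with 1 µm the two are numerically equal
CORTEX_THICKNESS_UM = 1.0


@dataclass(frozen=True)
class MechanicalParams:
    """Global mechanical constants of the tissue model.

    Attributes
    ----------
    adhesion_energy_density : float
        γσ, bond energy × bond surface density, Pa·µm (energy per unit facet
        area).  Default is of the order of cadherin bond energies times
        typical surface densities.
    lambda_osmotic : float
        λ = P₀V₀, Pa·µm³, with P₀ ≈ 500 Pa the free-solution osmotic pressure
        and V₀ = 1000 µm³.
    kbt_eff : float
        Effective temperature (k_BT)_eff, Pa·µm³ — the energy scale of active
        motility that governs Metropolis acceptance of energy-raising
        rearrangements.  The default, 2×10³ Pa·µm³ (= 2×10⁻¹⁵ J), is the work
        of a ~nN protrusion force over a ~µm displacement; it also keeps
        thermal area fluctuations (σ_A = √(kbt·A0/k) ≈ 44 µm² at k = 500 Pa·µm)
        below the systematic soft-vs-stiff area split, so mechanosensitive
        fate remains resolvable.
    p0 : float
        Baseline fate probability: death and division probability of a cell
        at the homeostatic mean area.
    """

    adhesion_energy_density: float = 0.05
    lambda_osmotic: float = 500.0 * V0_DEFAULT
    kbt_eff: float = 2.0e3
    p0: float = 0.01

    def __post_init__(self):
        if self.adhesion_energy_density < 0:
            raise ValueError("adhesion_energy_density must be >= 0")
        if not self.lambda_osmotic > 0:
            raise ValueError("lambda_osmotic must be > 0")
        if not self.kbt_eff > 0:
            raise ValueError("kbt_eff must be > 0")
        if not 0 < self.p0 < 0.5:
            raise ValueError(f"p0 must be in (0, 0.5), got {self.p0}")


@dataclass(frozen=True)
class Cell:
    """A point-cell: position, mechanical phenotype, free-solution geometry."""

    id: int
    position: np.ndarray       # µm, inside the box
    stiffness: float           # Pa; the heritable phenotype value
    V0: float = V0_DEFAULT     # µm³, free-solution volume
    A0: float = field(default=None)  # µm², free-solution (spherical) area

    def __post_init__(self):
        if not self.stiffness > 0:
            raise ValueError(f"stiffness must be > 0, got {self.stiffness}")
        if not self.V0 > 0:
            raise ValueError("V0 must be > 0")
        if self.A0 is None:
            object.__setattr__(self, "A0", sphere_equivalent_area(self.V0))

    @property
    def cortex_stiffness_k(self) -> float:
        """Areal cortex stiffness k (Pa·µm) = elastic modulus × cortex thickness."""
        return self.stiffness * CORTEX_THICKNESS_UM


def cell_energy(cell: Cell, geom: CellGeometry, params: MechanicalParams) -> float:
    """Mechanical energy (Pa·µm³) of one cell given its current geometry.

    The stretch term is >= 0, the adhesion term <= 0, and the osmotic term is
    positive when the cell is compressed below its free-solution volume.
    """
    if geom is None:
        raise ValueError(f"cell {cell.id} has no geometry")
    if not geom.volume > 0:
        raise ValueError(f"cell {cell.id}: non-positive volume {geom.volume}")
    A_i = geom.surface_area
    dA = A_i - cell.A0
    stretch = 0.5 * cell.cortex_stiffness_k * dA * dA / cell.A0
    adhesion = -0.5 * params.adhesion_energy_density * float(np.sum(geom.interface_areas))
    osmotic = -params.lambda_osmotic * np.log(geom.volume / cell.V0)
    return stretch + adhesion + osmotic


def tissue_energy(state) -> float:
    """Total mechanical energy: Σ U_i over all cells (Pa·µm³).

    Requires the state's cached tessellation to be current.
    """
    if state.stale:
        raise RuntimeError("tessellation is stale; call state.retessellate() first")
    return float(state.energies.sum())


def delta_energy(state, moved_cell_ids, new_positions) -> float:
    """Energy change of moving the given cells, by incremental recomputation.

    Only cells whose Voronoi geometry changes (the moved cells and their
    neighborhoods before and after the move) are re-evaluated; the state is
    left unmodified.  Agrees with a full recomputation to 1e-6 relative
    tolerance.
    """
    from . import _clip

    ids = np.asarray(moved_cell_ids, dtype=np.int64)
    newpos = np.asarray(new_positions, dtype=float).reshape(len(ids), 3)
    if state.stale:
        raise RuntimeError("tessellation is stale; call state.retessellate() first")
    n = state.n_cells
    if np.any(ids < 0) or np.any(ids >= n):
        raise ValueError("moved cell id out of range")
    L = state.box.edge_length
    oldpos = state.positions[ids].copy()
    buf = state._affected_buffers()
    delta, na, err = _clip.try_move(
        state.positions, state.cortex_k, L, state._R0,
        state.A0, state.V0,
        state.params.adhesion_energy_density, state.params.lambda_osmotic,
        state.volumes, state.surface_areas, state._nbr, state._nbrn,
        state._nbra, state._dmax, state.energies,
        ids, newpos, *buf, *state._clip_workspace())
    # always restore: this is a pure query
    state.positions[ids] = oldpos
    _clip.clear_affected(buf[0], na, buf[-1])
    if err != _clip.OK:
        raise RuntimeError(f"incremental geometry update failed (code {err})")
    return float(delta)
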