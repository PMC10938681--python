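"""Periodic 3D Voronoi tessellation of point-cells.

Each biological cell is represented by a single generating point inside a
periodic cubic box; its shape is the Voronoi polyhedron of that point.  The
tessellation partitions the box exactly, so cell volumes always sum to the box
volume — a property used as a standing self-check.

The production path clips each cell's polyhedron against the bisector planes
of nearby points (numba kernels in :mod:`patchytissue._clip`).  Configurations
too sparse for that construction (cells comparable in size to the box) fall
back to a scipy Voronoi diagram of explicitly replicated periodic images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _clip

__all__ = [
    "Box",
    "CellGeometry",
    "Tessellation",
    "sphere_equivalent_area",
    "tessellate",
]

#: points closer than this (µm, minimum image) are rejected as coincident
DUPLICATE_TOL = 1e-6

#: relative tolerance on the volume-partition identity
VOLUME_CONSERVATION_RTOL = 1e-6


@dataclass(frozen=True)
class Box:
    """Cubic periodic simulation domain.

    Parameters
    ----------
    edge_length : float
        Edge of the cube in µm.
    periodic : bool
        Always true in this package; kept explicit for provenance.
    """

    edge_length: float
    periodic: bool = True

    def __post_init__(self):
        if not self.edge_length > 0:
            raise ValueError(f"box edge_length must be > 0, got {self.edge_length}")
        if not self.periodic:
            raise ValueError("only periodic boxes are supported")

    @property
    def volume(self) -> float:
        return float(self.edge_length) ** 3


@dataclass(frozen=True)
class CellGeometry:
    """Per-cell polyhedral geometry extracted from a tessellation."""

    volume: float                    # µm³
    surface_area: float              # µm²
    neighbors: np.ndarray            # cell ids sharing a facet (own id = periodic self-contact)
    interface_areas: np.ndarray      # µm², aligned with ``neighbors``
    sphere_equivalent_area: float    # µm², area of the equal-volume sphere


class Tessellation:
    """Voronoi geometry of every cell in a periodic box.

    Holds flat arrays (volumes, surface areas, fixed-width neighbor tables) so
    the Monte-Carlo kernels can update entries in place; `cell(i)` returns a
    read-only per-cell view.
    """

    def __init__(self, box: Box, volumes, surface_areas, nbr, nbrn, nbra,
                 dmax):
        self.box = box
        self.volumes = volumes
        self.surface_areas = surface_areas
        self._nbr = nbr
        self._nbrn = nbrn
        self._nbra = nbra
        self._dmax = dmax

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def sphere_equivalent_areas(self) -> np.ndarray:
        return sphere_equivalent_area(self.volumes)

    def neighbors(self, i: int) -> np.ndarray:
        return self._nbr[i, : self._nbrn[i]].copy()

    def interface_areas(self, i: int) -> np.ndarray:
        return self._nbra[i, : self._nbrn[i]].copy()

    def interface_area(self, i: int, j: int) -> float:
        """Total shared area between cells ``i`` and ``j`` (0 if not adjacent).

        Under periodic boundaries a neighbor can contribute several facets
        (one per periodic image); their areas are summed here.
        """
        row = self._nbr[i, : self._nbrn[i]]
        return float(self._nbra[i, : self._nbrn[i]][row == j].sum())

    def adhesion_area(self, i: int) -> float:
        """Total interface area of cell ``i`` (Σ_j A_j, self-contacts included)."""
        return float(self._nbra[i, : self._nbrn[i]].sum())

    def cell(self, i: int) -> CellGeometry:
        if not 0 <= i < len(self):
            raise IndexError(f"no cell {i} in tessellation of {len(self)} cells")
        return CellGeometry(
            volume=float(self.volumes[i]),
            surface_area=float(self.surface_areas[i]),
            neighbors=self.neighbors(i),
            interface_areas=self.interface_areas(i),
            sphere_equivalent_area=float(sphere_equivalent_area(self.volumes[i])),
        )


def sphere_equivalent_area(volume):
    """Surface area of the sphere with the given volume.

    ``A_sp = 4π (3V / 4π)^(2/3)``, the area the cell would have in free
    solution where it is spherical; strictly increasing in ``V``.
    """
    v = np.asarray(volume, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be strictly positive")
    a = 4.0 * np.pi * (3.0 * v / (4.0 * np.pi)) ** (2.0 / 3.0)
    return float(a) if np.isscalar(volume) else a


def _min_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.rint(d / L)


def check_points(points: np.ndarray, box: Box) -> np.ndarray:
    """Validate a point set: shape, inside box, pairwise distinct."""
    pts = np.array(points, dtype=float, copy=True, order="C")
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be (n, 3), got {pts.shape}")
    n = pts.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    L = box.edge_length
    if np.any(pts < 0) or np.any(pts >= L):
        bad = int(np.nonzero(np.any((pts < 0) | (pts >= L), axis=1))[0][0])
        raise ValueError(f"point {bad} at {pts[bad]} lies outside the box [0, {L})³")
    diff = _min_image(pts[:, None, :] - pts[None, :, :], L)
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, np.inf)
    if d2.min() < DUPLICATE_TOL**2:
        i, j = np.unravel_index(np.argmin(d2), d2.shape)
        raise ValueError(
            f"coincident points: cells {min(i, j)} and {max(i, j)} are "
            f"{np.sqrt(d2[i, j]):.2e} µm apart (tolerance {DUPLICATE_TOL} µm)"
        )
    return pts


def default_candidate_radius(n: int, L: float) -> float:
    """Initial bisector search radius: ~2.6 mean point spacings, capped at L/2."""
    spacing = (L**3 / n) ** (1.0 / 3.0)
    return min(2.6 * spacing, 0.5 * L)


def tessellate_arrays(pos: np.ndarray, L: float):
    """Raw-array tessellation: returns (vol, sarea, nbr, nbrn, nbra, dmax)."""
    n = pos.shape[0]
    vol = np.empty(n)
    sarea = np.empty(n)
    nbr = np.empty((n, _clip.MAXN), np.int64)
    nbrn = np.zeros(n, np.int64)
    nbra = np.empty((n, _clip.MAXN))
    dmax = np.empty(n)
    R0 = default_candidate_radius(n, L)
    err = _clip.update_cells(pos, L, R0, np.arange(n), vol, sarea, nbr, nbrn,
                             nbra, dmax)
    if err == _clip.ERR_TIER2:
        return _tessellate_images(pos, L)
    if err != _clip.OK:
        raise RuntimeError(
            f"degenerate tessellation: clipping kernel failed (code {err})")
    total = vol.sum()
    if abs(total - L**3) > VOLUME_CONSERVATION_RTOL * L**3:
        raise RuntimeError(
            f"degenerate tessellation: cell volumes sum to {total:.6g}, "
            f"box volume is {L**3:.6g}")
    return vol, sarea, nbr, nbrn, nbra, dmax


def _tessellate_images(pos: np.ndarray, L: float):
    """Exact periodic Voronoi via explicit image replication (sparse path).

    Used when cells are comparable in size to the box, where the clipping
    kernels' locality assumptions fail.  Small n only; cost is O((kn)^2) in the
    number of replicated images k.
    """
    from scipy.spatial import ConvexHull, Voronoi

    n = pos.shape[0]
    reach = 2 if n <= 16 else 1
    offsets = [
        (ox, oy, oz)
        for ox in range(-reach, reach + 1)
        for oy in range(-reach, reach + 1)
        for oz in range(-reach, reach + 1)
    ]
    offsets.remove((0, 0, 0))
    blocks = [pos] + [pos + np.array(o, dtype=float) * L for o in offsets]
    allpts = np.vstack(blocks)
    vor = Voronoi(allpts)

    vol = np.empty(n)
    sarea = np.empty(n)
    nbr = np.empty((n, _clip.MAXN), np.int64)
    nbrn = np.zeros(n, np.int64)
    nbra = np.zeros((n, _clip.MAXN))
    dmax = np.empty(n)

    iface: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for (a, b), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in rv:
            continue
        for c, other in ((a, b), (b, a)):
            if c >= n:
                continue
            verts = vor.vertices[rv]
            rel = verts - verts[0]
            cross = np.zeros(3)
            for k in range(1, len(rel) - 1):
                cross += np.cross(rel[k], rel[k + 1])
            area = 0.5 * np.linalg.norm(cross)
            if area > _clip.FACET_AREA_MIN:
                iface[c].append((other % n, area))

    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError(
                f"degenerate tessellation: cell {i} unbounded after image "
                "replication")
        verts = vor.vertices[region]
        hull = ConvexHull(verts)
        vol[i] = hull.volume
        sarea[i] = hull.area
        dmax[i] = np.linalg.norm(verts - pos[i], axis=1).max()
        items = sorted(iface[i])
        if len(items) > _clip.MAXN:
            raise RuntimeError(f"cell {i} has {len(items)} neighbors (> {_clip.MAXN})")
        nbrn[i] = len(items)
        for q, (j, a) in enumerate(items):
            nbr[i, q] = j
            nbra[i, q] = a

    total = vol.sum()
    if abs(total - L**3) > VOLUME_CONSERVATION_RTOL * L**3:
        raise RuntimeError(
            f"degenerate tessellation: cell volumes sum to {total:.6g}, "
            f"box volume is {L**3:.6g}")
    return vol, sarea, nbr, nbrn, nbra, dmax


def tessellate(points, box: Box) -> Tessellation:
    """Periodic Voronoi tessellation of ``points`` in ``box``.

    Parameters
    ----------
    points : (n, 3) array
        Cell positions in µm, inside ``[0, L)³``; pairwise distinct.
    box : Box
        Periodic cubic domain.

    Returns
    -------
    Tessellation
        Per-cell volumes, surface areas, neighbor ids and shared facet areas.
        Volumes sum to the box volume to 1e-6 relative tolerance by
        construction (checked; violation raises ``RuntimeError``).
    """
    pts = check_points(points, box)
    vol, sarea, nbr, nbrn, nbra, dmax = tessellate_arrays(pts, box.edge_length)
    return Tessellation(box, vol, sarea, nbr, nbrn, nbra, dmax)
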