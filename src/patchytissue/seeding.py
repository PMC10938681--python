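"""Initial tissue construction.

Stiffness heterogeneity follows a log-normal distribution parameterized by its
arithmetic mean (500 Pa for a healthy population) and its mode; lowering the
mode at fixed mean widens the distribution.  Spatial arrangement is either
well-mixed (positions uniform, phenotypes i.i.d.) or mechanically clustered:
a few seed cells are scattered first and every subsequent cell is placed near
the existing cell with the most similar stiffness, so mechanically alike cells
end up in contiguous patches while the population-level stiffness distribution
is untouched.  Fewer seed cells produce fewer, larger patches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .energy import MechanicalParams
from .geometry import DUPLICATE_TOL, Box
from .state import TissueState

__all__ = [
    "StiffnessDistributionSpec",
    "ClusteringSpec",
    "lognormal_params",
    "seed_homogeneous",
    "seed_clustered",
]

log = logging.getLogger(__name__)

#: stiffness draws outside this range (Pa) are redrawn; keeps phenotypes within
#: the experimentally measured cell elastic-modulus range without distorting
#: the bulk of the distribution
STIFFNESS_MIN_PA = 50.0
STIFFNESS_MAX_PA = 1500.0


def lognormal_params(mean: float, mode: float) -> tuple[float, float]:
    """Log-parameters (µ, s) of the unique log-normal with given mean and mode.

    From mean = exp(µ + s²/2) and mode = exp(µ − s²):
    ``s² = (2/3) ln(mean/mode)`` and ``µ = ln(mode) + s²``.
    """
    if not 0 < mode < mean:
        raise ValueError(
            f"need 0 < mode < mean (a log-normal's mode lies below its mean); "
            f"got mode={mode}, mean={mean}")
    s2 = (2.0 / 3.0) * np.log(mean / mode)
    s = np.sqrt(s2)
    mu = np.log(mode) + s2
    return float(mu), float(s)


@dataclass(frozen=True)
class StiffnessDistributionSpec:
    """Log-normal cell-stiffness distribution, fixed mean, variable mode.

    ``mean`` is the healthy-population average stiffness (Pa); the mode
    controls the spread (lower mode at fixed mean = higher variance).
    ``s = 0`` degenerate distributions are expressed by ``mode == None``
    via :meth:`uniform`.
    """

    mean: float = 500.0
    mode: float = 465.0
    mu: float = field(init=False)
    s: float = field(init=False)

    def __post_init__(self):
        mu, s = lognormal_params(self.mean, self.mode)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "s", s)

    def sample(self, n: int, rng) -> np.ndarray:
        """Draw n stiffness values (Pa); out-of-range draws are redrawn."""
        out = rng.lognormal(self.mu, self.s, size=n)
        bad = (out < STIFFNESS_MIN_PA) | (out > STIFFNESS_MAX_PA)
        n_redrawn = 0
        while bad.any():
            n_redrawn += int(bad.sum())
            out[bad] = rng.lognormal(self.mu, self.s, size=int(bad.sum()))
            bad = (out < STIFFNESS_MIN_PA) | (out > STIFFNESS_MAX_PA)
        if n_redrawn:
            log.debug("redrew %d out-of-range stiffness draws", n_redrawn)
        return out


@dataclass(frozen=True)
class ClusteringSpec:
    """Mechanical-similarity clustering of the initial arrangement.

    ``n_seeds`` scattered cells are placed first; every later cell is placed
    within ``placement_radius`` (µm, about one cell length) of the existing
    cell closest to it in stiffness.  ``n_seeds = 0`` means no clustering.
    """

    n_seeds: int = 8
    placement_radius: float = 10.0
    max_rejects: int = 100

    def __post_init__(self):
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1 (use seed_homogeneous for none)")
        if not self.placement_radius > 0:
            raise ValueError("placement_radius must be > 0")


def _distinct_uniform(n: int, L: float, rng) -> np.ndarray:
    """n uniform positions in [0, L)^3, pairwise farther than the duplicate tolerance."""
    pos = rng.uniform(0.0, L, size=(n, 3))
    # collisions have probability ~0; resolve by redraw if they do occur
    for _ in range(100):
        d = pos[:, None, :] - pos[None, :, :]
        d -= L * np.rint(d / L)
        d2 = np.einsum("ijk,ijk->ij", d, d)
        np.fill_diagonal(d2, np.inf)
        bad = np.unique(np.nonzero(d2 < DUPLICATE_TOL**2)[0])
        if bad.size == 0:
            return pos
        pos[bad] = rng.uniform(0.0, L, size=(bad.size, 3))
    raise RuntimeError("could not draw distinct positions")


def seed_homogeneous(n_cells: int, box: Box, dist: StiffnessDistributionSpec,
                     rng, params: MechanicalParams | None = None,
                     stiffness: np.ndarray | None = None) -> TissueState:
    """Well-mixed tissue: uniform random positions, i.i.d. stiffness.

    ``stiffness`` may be supplied explicitly (same rng-stream contract as
    :func:`seed_clustered`: values are drawn before any placement).
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if stiffness is None:
        stiffness = dist.sample(n_cells, rng)
    pos = _distinct_uniform(n_cells, box.edge_length, rng)
    return TissueState(pos, stiffness, box, params)


def seed_clustered(n_cells: int, box: Box, dist: StiffnessDistributionSpec,
                   clustering: ClusteringSpec, rng,
                   params: MechanicalParams | None = None,
                   stiffness: np.ndarray | None = None) -> TissueState:
    """Mechanically clustered tissue.

    Stiffness values are drawn for all cells first (so the phenotype multiset
    is identical to a well-mixed tissue built from the same stream); the first
    ``n_seeds`` cells are scattered uniformly, and each remaining cell is
    placed uniformly within the placement radius of the existing cell most
    similar in stiffness.  Placement failing ``max_rejects`` times widens the
    radius by 1.5x (logged) and retries.
    """
    if clustering.n_seeds >= n_cells:
        return seed_homogeneous(n_cells, box, dist, rng, params,
                                stiffness=stiffness)
    L = box.edge_length
    if stiffness is None:
        stiffness = dist.sample(n_cells, rng)
    nseed = clustering.n_seeds
    pos = np.empty((n_cells, 3))
    pos[:nseed] = _distinct_uniform(nseed, L, rng)

    for i in range(nseed, n_cells):
        placed = pos[:i]
        anchor = int(np.argmin(np.abs(stiffness[:i] - stiffness[i])))
        radius = clustering.placement_radius
        rejects = 0
        while True:
            # uniform in the ball of this radius around the anchor
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = radius * rng.random() ** (1.0 / 3.0)
            cand = (pos[anchor] + r * u) % L
            d = placed - cand
            d -= L * np.rint(d / L)
            if (np.einsum("ij,ij->i", d, d) >= DUPLICATE_TOL**2).all():
                pos[i] = cand
                break
            rejects += 1
            if rejects >= clustering.max_rejects:
                radius *= 1.5
                rejects = 0
                log.info("cell %d: widening placement radius to %.2f µm",
                         i, radius)
    return TissueState(pos, stiffness, box, params)
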