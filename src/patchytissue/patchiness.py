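"""Patchiness index: global vs. local stiffness heterogeneity.

Borrowed from landscape ecology: a tissue is "patchy" when its cell population
is diverse overall but locally uniform — mechanically similar cells sit next
to each other in patches.  Heterogeneity is the Shannon entropy of cell
stiffness values binned into fixed-width bins, normalized by ``ln N`` of the
population sampled::

    c = [ -Σ P_i ln P_i / ln N_total ]  /  mean_w[ -Σ P_i ln P_i / ln n_w ]

The numerator uses the whole tissue; the denominator averages the same
statistic over cubic moving windows (periodic wrap, fixed stride).  ``c = 1``
when the window is the whole box; well-mixed tissues give ``c < 1`` (local
samples are as diverse as the whole but smaller, inflating the normalized
entropy); segregated tissues push local entropy to 0 and ``c → ∞``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Box

__all__ = [
    "HeterogeneityResult",
    "bin_fractions",
    "normalized_entropy",
    "local_heterogeneities",
    "patchiness_index",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOW_UM = 40.0
DEFAULT_STRIDE_UM = 10.0   # ~ one cell length
DEFAULT_BIN_PA = 10.0


def bin_fractions(values, bin_width: float = DEFAULT_BIN_PA) -> np.ndarray:
    """Fractions of the sample per occupied stiffness bin.

    Bins are ``[m·w, (m+1)·w)`` anchored at 0 Pa.  Only occupied bins are
    returned; fractions sum to 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot bin an empty sample")
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    idx = np.floor(v / bin_width).astype(np.int64)
    _, counts = np.unique(idx, return_counts=True)
    return counts / v.size


def normalized_entropy(fractions, n_samples: int) -> float:
    """Shannon entropy of the bin fractions, normalized by ln(n_samples).

    Zero when a single bin is occupied; 1 when every one of ``n_samples``
    values sits alone in its own bin.
    """
    if n_samples < 2:
        raise ValueError("normalized entropy needs n_samples >= 2 "
                         "(ln 1 = 0 denominator)")
    p = np.asarray(fractions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    p = p[p > 0]
    H = float(-(p * np.log(p)).sum())
    return H / math.log(n_samples)


def _coerce(state_or_arrays):
    """Accept a TissueState or a (positions, stiffness, box) triple."""
    if hasattr(state_or_arrays, "positions"):
        s = state_or_arrays
        return s.positions, s.stiffness, s.box
    pos, stiff, box = state_or_arrays
    if not isinstance(box, Box):
        box = Box(float(box))
    return np.asarray(pos, float), np.asarray(stiff, float), box


def _window_grid(L: float, stride: float) -> np.ndarray:
    m = max(1, int(math.floor(L / stride + 1e-9)))
    return np.arange(m) * stride


def local_heterogeneities(state, window_edge: float = DEFAULT_WINDOW_UM,
                          stride: float = DEFAULT_STRIDE_UM,
                          bin_width: float = DEFAULT_BIN_PA,
                          return_windows: bool = False):
    """Normalized entropy inside every cubic moving window.

    Windows of edge ``window_edge`` are placed on the 3D stride grid with
    periodic wrap; windows holding fewer than 2 cells carry no heterogeneity
    information and are skipped (logged).
    """
    pos, stiff, box = _coerce(state)
    L = box.edge_length
    if window_edge > L:
        raise ValueError(f"window edge {window_edge} exceeds box edge {L}")
    if not stride > 0:
        raise ValueError("stride must be > 0")
    grid = _window_grid(L, stride)
    p = pos % L
    values = []
    origins = []
    counts = []
    n_skipped = 0
    for x0 in grid:
        inx = ((p[:, 0] - x0) % L) < window_edge
        for y0 in grid:
            iny = inx & (((p[:, 1] - y0) % L) < window_edge)
            for z0 in grid:
                mask = iny & (((p[:, 2] - z0) % L) < window_edge)
                nw = int(mask.sum())
                if nw < 2:
                    n_skipped += 1
                    continue
                h = normalized_entropy(bin_fractions(stiff[mask], bin_width), nw)
                values.append(h)
                origins.append((x0, y0, z0))
                counts.append(nw)
    if n_skipped:
        log.debug("skipped %d windows with < 2 cells", n_skipped)
    if not values:
        raise ValueError("no window contains >= 2 cells")
    if return_windows:
        return np.array(values), np.array(origins), np.array(counts), n_skipped
    return np.array(values)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Global and windowed heterogeneity of one tissue configuration.

    ``patchiness_index`` is +inf when the tissue is globally diverse but every
    window is pure (perfect segregation), and NaN with ``undefined`` set when
    the tissue is mechanically uniform (0/0).
    """

    global_heterogeneity: float
    local_heterogeneities: np.ndarray
    patchiness_index: float
    window_edge: float
    stride: float
    bin_width: float
    window_origins: np.ndarray = field(repr=False, default=None)
    window_counts: np.ndarray = field(repr=False, default=None)
    n_windows_skipped: int = 0
    undefined: bool = False

    @property
    def mean_local_heterogeneity(self) -> float:
        return float(self.local_heterogeneities.mean())

    def to_dict(self) -> dict:
        return {
            "global_heterogeneity": self.global_heterogeneity,
            "mean_local_heterogeneity": self.mean_local_heterogeneity,
            "patchiness_index": self.patchiness_index,
            "window_edge_um": self.window_edge,
            "stride_um": self.stride,
            "bin_width_pa": self.bin_width,
            "n_windows": int(len(self.local_heterogeneities)),
            "n_windows_skipped": self.n_windows_skipped,
            "undefined": self.undefined,
        }


def patchiness_index(state, window_edge: float = DEFAULT_WINDOW_UM,
                     stride: float = DEFAULT_STRIDE_UM,
                     bin_width: float = DEFAULT_BIN_PA) -> HeterogeneityResult:
    """Patchiness index c = global / mean local normalized entropy."""
    pos, stiff, box = _coerce(state)
    g = normalized_entropy(bin_fractions(stiff, bin_width), stiff.size)
    loc, origins, counts, skipped = local_heterogeneities(
        (pos, stiff, box), window_edge, stride, bin_width, return_windows=True)
    mean_local = float(loc.mean())
    undefined = False
    if mean_local > 0:
        c = g / mean_local
    elif g > 0:
        c = math.inf
    else:
        c = math.nan
        undefined = True
    return HeterogeneityResult(
        global_heterogeneity=g, local_heterogeneities=loc,
        patchiness_index=c, window_edge=window_edge, stride=stride,
        bin_width=bin_width, window_origins=origins, window_counts=counts,
        n_windows_skipped=skipped, undefined=undefined)
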