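"""Cartesian domain decomposition with ghost layers and checkerboard colors.

The image is cut into disjoint rectangular blocks, one per rank.  Each rank
stores its block plus a ghost frame of width g replicating neighbouring
blocks (cells beyond the image boundary are permanent background).  Blocks
are two-colored like a checkerboard so that face-adjacent blocks always
differ in color.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import LABEL_DTYPE
from .energy import EnergyParams

BLACK = "black"
WHITE = "white"


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainGrid:
    """A Cartesian decomposition of the image into P = prod(dims) blocks.

    Ranks are numbered in raster order of their grid coordinates; remainder
    pixels go to the last block along each axis.
    """

    shape: Tuple[int, ...]
    dims: Tuple[int, ...]
    g: int

    def __post_init__(self):
        if len(self.dims) != len(self.shape):
            raise ValueError("dims and shape dimensionality differ")
        for ext, d in zip(self.shape, self.dims):
            if d < 1 or d > ext:
                raise ValueError(f"invalid subdomain count {d} for extent {ext}")
        for ext, d in zip(self.shape, self.dims):
            base = ext // d
            if base < max(2 * self.g, 1):
                raise ValueError(
                    f"block extent {base} too small for ghost width {self.g}")

    @property
    def n_ranks(self) -> int:
        return int(np.prod(self.dims))

    def coords_of(self, rank: int) -> Tuple[int, ...]:
        return tuple(int(c) for c in np.unravel_index(rank, self.dims))

    def rank_of(self, coords: Sequence[int]) -> int:
        return int(np.ravel_multi_index(tuple(coords), self.dims))

    def block(self, rank: int) -> Tuple[slice, ...]:
        """Owned global slab of a rank."""
        coords = self.coords_of(rank)
        out = []
        for ext, d, c in zip(self.shape, self.dims, coords):
            base = ext // d
            start = c * base
            stop = (c + 1) * base if c < d - 1 else ext
            out.append(slice(start, stop))
        return tuple(out)

    def neighbors(self, rank: int) -> List[int]:
        """All ranks whose blocks touch this one, faces and corners."""
        coords = self.coords_of(rank)
        out = []
        for delta in np.ndindex(*(3,) * len(self.dims)):
            d = tuple(int(x) - 1 for x in delta)
            if all(v == 0 for v in d):
                continue
            nb = tuple(c + v for c, v in zip(coords, d))
            if all(0 <= c < dd for c, dd in zip(nb, self.dims)):
                out.append(self.rank_of(nb))
        return sorted(out)


def decompose(shape: Sequence[int], dims: Sequence[int], g: int) -> DomainGrid:
    """Validated Cartesian decomposition (deterministic block boundaries)."""
    return DomainGrid(tuple(int(s) for s in shape),
                      tuple(int(d) for d in dims), int(g))


def ghost_width(p: EnergyParams) -> int:
    """Ghost-layer width from the energy kernel radius.

    g = max(R_kappa, R if piecewise smooth else 0) + 1; the +1 covers the
    one-pixel topology neighbourhood.
    """
    r = p.radius if p.model == "ps" else 0
    return max(p.r_kappa, r) + 1


def checkerboard_color(grid_coords: Sequence[int]) -> str:
    """Black iff the sum of subdomain grid coordinates is even."""
    return BLACK if sum(int(c) for c in grid_coords) % 2 == 0 else WHITE


def auto_dims(shape: Sequence[int], n_ranks: int) -> Tuple[int, ...]:
    """Deterministic near-cubic factorization: largest prime factors are
    assigned to the longest remaining block axes."""
    factors = []
    n = int(n_ranks)
    f = 2
    while f * f <= n:
        while n % f == 0:
            factors.append(f)
            n //= f
        f += 1
    if n > 1:
        factors.append(n)
    dims = [1] * len(shape)
    for f in sorted(factors, reverse=True):
        ax = int(np.argmax([s / d for s, d in zip(shape, dims)]))
        dims[ax] *= f
    return tuple(dims)


# ---------------------------------------------------------------------------
# per-rank state
# ---------------------------------------------------------------------------

@dataclass
class SubDomainState:
    """One rank's sub-image, label block with ghost frame, and queues.

    Local arrays span the owned block plus a ghost frame of width g on
    every side; frame cells beyond the image boundary hold intensity 0 and
    label 0 (permanent background).  Ghost cells mirror the owning rank's
    values as of the last exchange and are never authoritative locally.
    """

    rank: int
    coords: Tuple[int, ...]
    block: Tuple[slice, ...]
    color: str
    g: int
    image_loc: np.ndarray
    labels_loc: np.ndarray
    inbox: List = field(default_factory=list)
    hotpart: bool = False
    counters: Dict[str, int] = field(default_factory=dict)

    @property
    def owned(self) -> Tuple[slice, ...]:
        """Owned region in local coordinates."""
        return tuple(slice(self.g, self.g + (b.stop - b.start))
                     for b in self.block)

    @property
    def origin(self) -> Tuple[int, ...]:
        """Global coordinate of local cell (0,...,0) (may be negative)."""
        return tuple(b.start - self.g for b in self.block)

    def out_of_image_mask(self, image_shape: Sequence[int]) -> np.ndarray:
        """Local cells that lie beyond the image boundary."""
        out = np.zeros(self.labels_loc.shape, dtype=bool)
        for ax, (o, ext, sz) in enumerate(zip(self.origin, image_shape,
                                              self.labels_loc.shape)):
            idx = np.arange(sz) + o
            bad = (idx < 0) | (idx >= ext)
            sl = [None] * self.labels_loc.ndim
            sl[ax] = slice(None)
            out |= bad[tuple(sl)]
        return out

    def owned_labels(self) -> np.ndarray:
        return self.labels_loc[self.owned]

    def to_local(self, global_slices: Sequence[slice]) -> Tuple[slice, ...]:
        return tuple(slice(s.start - o, s.stop - o)
                     for s, o in zip(global_slices, self.origin))

    def owns_flat(self, flat: int, shape: Tuple[int, ...]) -> bool:
        c = np.unravel_index(flat, shape)
        return all(b.start <= v < b.stop for v, b in zip(c, self.block))


def make_states(image: np.ndarray, labels: np.ndarray,
                grid: DomainGrid, pad: Optional[int] = None
                ) -> List[SubDomainState]:
    """Scatter the global fields into per-rank local arrays (with ghosts).

    ``pad`` widens the stored frame beyond the grid's ghost width (used by
    the piecewise-smooth model, whose exact energy differences need label
    data up to 2R+1 away); it must not exceed the neighbouring block extents.
    """
    states = []
    for rank in range(grid.n_ranks):
        blk = grid.block(rank)
        coords = grid.coords_of(rank)
        g = grid.g if pad is None else int(pad)
        if any((b.stop - b.start) < g for b in grid.block(rank)):
            raise ValueError("frame width exceeds a block extent")
        loc_shape = tuple((b.stop - b.start) + 2 * g for b in blk)
        img_loc = np.zeros(loc_shape, dtype=np.float64)
        # cells beyond the image boundary carry the -1 sentinel so that the
        # move enumerator treats them exactly like the sequential driver
        # treats out-of-grid neighbours
        lab_loc = np.full(loc_shape, -1, dtype=LABEL_DTYPE)
        # copy the intersection of the padded frame with the image
        src = tuple(slice(max(b.start - g, 0), min(b.stop + g, s))
                    for b, s in zip(blk, image.shape))
        dst = tuple(slice(s.start - (b.start - g), s.stop - (b.start - g))
                    for s, b in zip(src, blk))
        img_loc[dst] = image[src]
        lab_loc[dst] = labels[src]
        states.append(SubDomainState(rank, coords, blk,
                                     checkerboard_color(coords), g,
                                     img_loc, lab_loc))
    return states


def gather(states: List[SubDomainState], grid: DomainGrid,
           field_name: str = "labels") -> np.ndarray:
    """Reassemble the global field from owned blocks."""
    if field_name == "labels":
        out = np.zeros(grid.shape, dtype=LABEL_DTYPE)
        for s in states:
            out[s.block] = s.labels_loc[s.owned]
    else:
        out = np.zeros(grid.shape, dtype=np.float64)
        for s in states:
            out[s.block] = s.image_loc[s.owned]
    return out


def _intersect(a: Sequence[slice], b: Sequence[slice]) -> Optional[Tuple[slice, ...]]:
    out = []
    for x, y in zip(a, b):
        lo, hi = max(x.start, y.start), min(x.stop, y.stop)
        if lo >= hi:
            return None
        out.append(slice(lo, hi))
    return tuple(out)


def exchange_ghosts(states: List[SubDomainState], grid: DomainGrid,
                    field_name: str = "labels") -> int:
    """Refresh every ghost cell from its owning rank (faces and corners).

    Returns the number of point-to-point messages (nonempty slab copies).
    In the simulated runtime delivery is atomic between rounds: all copies
    read the owners' pre-exchange arrays, which are authoritative anyway.
    """
    attr = "labels_loc" if field_name == "labels" else "image_loc"
    messages = 0
    for s in states:
        frame = tuple(slice(b.start - s.g, b.stop + s.g) for b in s.block)
        for nb in grid.neighbors(s.rank):
            other = states[nb]
            inter = _intersect(frame, other.block)
            if inter is None:
                continue
            dst = s.to_local(inter)
            src = other.to_local(inter)
            getattr(s, attr)[dst] = getattr(other, attr)[src]
            messages += 1
    return messages
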