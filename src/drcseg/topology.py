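"""Digital-topology control for single-pixel relabelings.

Foreground regions must stay face-connected; splits and fusions are allowed
when the energy favors them, and are detected locally from the punctured
full neighborhood of the moved pixel.  The background may change its
topology freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, List, Tuple

import numpy as np
from scipy import ndimage

from .core import Connectivity, as_labels, face_structure

Pixel = Tuple[int, ...]

SIMPLE = "simple"
SPLIT = "split"
FUSE = "fuse"
FORBIDDEN = "forbidden"


@dataclass(frozen=True)
class MoveTopology:
    """Classification of a candidate relabeling.

    kind            : simple | split | fuse | forbidden
    affected_labels : labels whose pixel sets the move touches
    n_components    : local component count of the donor region (split arity)
    fuse_labels     : FG labels the move would join with the target label
    """

    kind: str
    affected_labels: FrozenSet[int] = frozenset()
    n_components: int = 1
    fuse_labels: FrozenSet[int] = frozenset()


@lru_cache(maxsize=None)
def _neighborhood_graph(ndim: int, face_only: bool):
    """Punctured-neighborhood cells and their internal adjacency.

    Cells are the full-neighborhood offsets; two cells are adjacent when
    they differ by a face step (FG connectivity) or any step (BG).
    """
    conn = Connectivity.from_ndim(ndim)
    cells = list(conn.bg_neighbors)
    index = {c: i for i, c in enumerate(cells)}
    steps = conn.fg_neighbors if face_only else conn.bg_neighbors
    adj: List[List[int]] = [[] for _ in cells]
    for i, c in enumerate(cells):
        for s in steps:
            d = tuple(a + b for a, b in zip(c, s))
            j = index.get(d)
            if j is not None:
                adj[i].append(j)
    face_cells = [index[c] for c in conn.fg_neighbors]
    return cells, adj, face_cells


def topological_number(labels, x, l: int, conn: Connectivity | None = None) -> int:
    """Number of l-components of the punctured full neighborhood of x that
    are face-adjacent to x.

    FG labels (l > 0) use face connectivity between neighborhood cells, the
    background uses full connectivity.  Cells outside the grid count as
    background.
    """
    lab = labels if isinstance(labels, np.ndarray) else as_labels(labels)
    conn = conn or Connectivity.from_ndim(lab.ndim)
    x = tuple(int(c) for c in x)
    cells, adj, face_cells = _neighborhood_graph(lab.ndim, face_only=l > 0)
    mask = []
    for c in cells:
        y = tuple(a + b for a, b in zip(x, c))
        if all(0 <= v < s for v, s in zip(y, lab.shape)):
            mask.append(int(lab[y]) == l)
        else:
            mask.append(l == 0)
    seen = [False] * len(cells)
    count = 0
    for start in range(len(cells)):
        if not mask[start] or seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = [start]
        while stack:
            i = stack.pop()
            for j in adj[i]:
                if mask[j] and not seen[j]:
                    seen[j] = True
                    stack.append(j)
                    comp.append(j)
        if any(i in face_cells for i in comp):
            count += 1
    return count


def _face_neighbor_labels(lab: np.ndarray, x: Pixel) -> List[int]:
    out = []
    for ax in range(lab.ndim):
        for d in (-1, 1):
            y = list(x)
            y[ax] += d
            if 0 <= y[ax] < lab.shape[ax]:
                out.append(int(lab[tuple(y)]))
            else:
                out.append(0)
    return out


def classify_move(labels, x, l_from: int, l_to: int,
                  conn: Connectivity | None = None,
                  merge_ok: bool = True) -> MoveTopology:
    """Classify relabeling pixel x from l_from to l_to.

    - simple: the donor region stays locally connected and no disallowed
      fusion is created (removing the last pixel of a region is simple and
      kills the region);
    - split: the donor's punctured neighborhood splits into several
      face-components (confirmed by flood fill at execution time — a pixel
      on a ring has topological number 2 but its removal does not split);
    - fuse: the target pixel ends face-adjacent to other FG labels, which
      are joined with the target label; requires ``merge_ok``;
    - forbidden: a fusion that ``merge_ok`` disallows.
    """
    lab = as_labels(labels)
    conn = conn or Connectivity.from_ndim(lab.ndim)
    x = tuple(int(c) for c in x)
    if l_from == l_to:
        raise ValueError("l_from and l_to must differ")
    if int(lab[x]) != l_from:
        raise ValueError("pixel does not carry l_from")

    affected = {l_from, l_to}
    fuse_labels: set = set()
    if l_to > 0:
        for m in _face_neighbor_labels(lab, x):
            if m > 0 and m != l_to:
                fuse_labels.add(m)
    if fuse_labels and not merge_ok:
        return MoveTopology(FORBIDDEN, frozenset(affected | fuse_labels),
                            fuse_labels=frozenset(fuse_labels))

    n_comp = 1
    if l_from > 0:
        t = topological_number(lab, x, l_from, conn)
        if t > 1:
            n_comp = t
    if fuse_labels:
        return MoveTopology(FUSE, frozenset(affected | fuse_labels),
                            n_components=n_comp,
                            fuse_labels=frozenset(fuse_labels))
    if n_comp > 1:
        return MoveTopology(SPLIT, frozenset(affected), n_components=n_comp)
    return MoveTopology(SIMPLE, frozenset(affected))


def split_components(labels, l: int) -> List[np.ndarray]:
    """Face-connected components of region l, as (k, ndim) coordinate arrays.

    Deterministic order: component containing the lexicographically smallest
    pixel first (raster first-encounter order of the flood fill).
    """
    lab = as_labels(labels)
    mask = lab == l
    if not np.any(mask):
        raise KeyError(f"unknown label {l}")
    comp, n = ndimage.label(mask, structure=face_structure(lab.ndim))
    return [np.argwhere(comp == i + 1) for i in range(n)]


# ---------------------------------------------------------------------------
# vectorized classification used by the move enumerator
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _cell_adjacency_matrix(ndim: int) -> np.ndarray:
    """Boolean face-adjacency among the punctured-neighborhood cells."""
    cells, adj, _ = _neighborhood_graph(ndim, face_only=True)
    n = len(cells)
    m = np.zeros((n, n), dtype=bool)
    for i, js in enumerate(adj):
        for j in js:
            m[i, j] = True
    return m


@lru_cache(maxsize=None)
def _face_cell_indices(ndim: int) -> np.ndarray:
    _, _, face_cells = _neighborhood_graph(ndim, face_only=True)
    return np.asarray(face_cells)


@lru_cache(maxsize=None)
def _padded_adjacency(ndim: int) -> np.ndarray:
    """(ncells, max_degree) face-neighbour cell indices, padded with self."""
    cells, adj, _ = _neighborhood_graph(ndim, face_only=True)
    deg = max(len(a) for a in adj)
    out = np.empty((len(cells), deg), dtype=np.int64)
    for i, js in enumerate(adj):
        row = list(js) + [i] * (deg - len(js))
        out[i] = row
    return out


def batch_topological_numbers(nb_full: np.ndarray, l_from: np.ndarray) -> np.ndarray:
    """Donor-region topological numbers for many moves at once.

    nb_full : (n_moves, n_cells) labels of the punctured full neighborhood
              (out-of-grid cells already set to 0), cells in the order of
              ``Connectivity.bg_neighbors``.
    l_from  : (n_moves,) donor labels (FG).

    Uses iterative min-label propagation over the fixed cell adjacency —
    equivalent to counting face-connected components per neighborhood and
    keeping those with a face-adjacent cell.
    """
    nm, ncells = nb_full.shape
    ndim = _ndim_from_cells(ncells)
    mask = nb_full == np.asarray(l_from)[:, None]
    adj = _padded_adjacency(ndim)
    sentinel = np.int8(ncells)
    comp = np.where(mask, np.arange(ncells, dtype=np.int8)[None, :], sentinel)
    # longest induced path in the punctured 8/26-neighborhood is < ncells
    for _ in range(ncells):
        gathered = comp[:, adj]            # (nm, ncells, deg)
        best = np.minimum(comp, gathered.min(axis=2))
        best = np.where(mask, best, sentinel)
        if np.array_equal(best, comp):
            break
        comp = best
    face_idx = _face_cell_indices(ndim)
    roots = comp[:, face_idx]
    fmask = mask[:, face_idx]
    t = np.zeros(nm, dtype=np.int64)
    for k in range(len(face_idx)):
        first = fmask[:, k].copy()
        for kk in range(k):
            first &= ~(fmask[:, kk] & (roots[:, kk] == roots[:, k]))
        t += first
    return t


def _ndim_from_cells(ncells: int) -> int:
    return 2 if ncells == 8 else 3
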