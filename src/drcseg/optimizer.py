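"""Sequential discrete region competition driver.

Each iteration enumerates all candidate single-pixel relabelings along the
contours, prices them with exact energy differences, builds the undirected
graph of causally dependent moves (moves sharing a pixel), selects the best
move per maximal connected sub-graph, and executes the selections in a
deterministic order with per-move topological re-validation.  Oscillations
near convergence are damped by halving the fraction of concurrently
accepted moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core import (Connectivity, RegionStats, as_image, as_labels,
                   face_structure, neighbor_label_stack, normalize_labels,
                   perimeter_pairs)
from .energy import (EnergyParams, EnergyTrace, PSMaps, pc_data_delta,
                     ps_move_delta, total_energy)
from .topology import (FORBIDDEN, FUSE, SIMPLE, SPLIT, MoveTopology,
                       batch_topological_numbers, classify_move)

Pixel = Tuple[int, ...]

K_SIMPLE, K_SPLIT, K_FUSE, K_FORBIDDEN = 0, 1, 2, 3
_KIND_NAMES = {K_SIMPLE: SIMPLE, K_SPLIT: SPLIT, K_FUSE: FUSE,
               K_FORBIDDEN: FORBIDDEN}


# ---------------------------------------------------------------------------
# move containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Move:
    """A candidate relabeling of one pixel, with its energy difference."""

    pixel: Pixel
    l_from: int
    l_to: int
    delta_e: float
    kind: str = SIMPLE
    src: Optional[Pixel] = None


class MoveArrays:
    """Struct-of-arrays move list used by the vectorized driver."""

    __slots__ = ("v", "src", "l_from", "l_to", "de", "kind", "ncomp", "shape")

    def __init__(self, shape, v, src, l_from, l_to, de, kind, ncomp):
        self.shape = shape
        self.v = v
        self.src = src
        self.l_from = l_from
        self.l_to = l_to
        self.de = de
        self.kind = kind
        self.ncomp = ncomp

    def __len__(self) -> int:
        return len(self.v)

    def to_moves(self) -> List[Move]:
        out = []
        for i in range(len(self.v)):
            out.append(Move(tuple(int(c) for c in np.unravel_index(self.v[i], self.shape)),
                            int(self.l_from[i]), int(self.l_to[i]),
                            float(self.de[i]), _KIND_NAMES[int(self.kind[i])],
                            tuple(int(c) for c in np.unravel_index(self.src[i], self.shape))))
        return out

    @classmethod
    def from_moves(cls, moves: Sequence[Move], shape) -> "MoveArrays":
        n = len(moves)
        v = np.empty(n, dtype=np.int64)
        src = np.empty(n, dtype=np.int64)
        lf = np.empty(n, dtype=np.int64)
        lt = np.empty(n, dtype=np.int64)
        de = np.empty(n, dtype=np.float64)
        kind = np.zeros(n, dtype=np.int8)
        names = {v_: k_ for k_, v_ in _KIND_NAMES.items()}
        for i, m in enumerate(moves):
            v[i] = np.ravel_multi_index(m.pixel, shape)
            src[i] = np.ravel_multi_index(m.src if m.src is not None else m.pixel, shape)
            lf[i], lt[i], de[i] = m.l_from, m.l_to, m.delta_e
            kind[i] = names.get(m.kind, K_SIMPLE)
        return cls(shape, v, src, lf, lt, de, kind, np.ones(n, dtype=np.int8))


@dataclass
class MoveGraph:
    """Moves partitioned into maximal connected sub-graphs.

    Moves are undirected edges between their target pixel and source
    particle pixel; sub-graphs are the connected components of the induced
    pixel graph, ordered by their smallest member pixel.
    """

    arrays: MoveArrays
    comp: np.ndarray          # component id per move, 0..n_components-1

    @property
    def n_components(self) -> int:
        return int(self.comp.max()) + 1 if len(self.comp) else 0

    def components(self) -> List[List[int]]:
        out: List[List[int]] = [[] for _ in range(self.n_components)]
        for i, c in enumerate(self.comp):
            out[int(c)].append(i)
        return out


@dataclass
class OscillationState:
    """Sliding window of recent acceptances and the damping fraction.

    Beyond halving the acceptance fraction, persistent two-cycles (the same
    relabeling executed back and forth ``blacklist_after`` times in each
    direction) are frozen for the rest of the run; this guarantees
    termination even when energy-difference estimates are inexact near
    subdomain boundaries, at the cost of leaving the oscillating pixels at
    one of their two alternative positions.
    """

    window_size: int = 10
    f_min: float = 0.05
    acceptance_fraction: float = 1.0
    window: List[Set[Tuple[int, int, int]]] = field(default_factory=list)
    flagged: bool = False
    blacklist_after: int = 4
    exec_counts: Dict[Tuple[int, int, int], int] = field(default_factory=dict)
    blacklist: Set[Tuple[int, int, int]] = field(default_factory=set)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _flat_offsets(shape, offsets) -> np.ndarray:
    strides = np.ones(len(shape), dtype=np.int64)
    for a in range(len(shape) - 2, -1, -1):
        strides[a] = strides[a + 1] * shape[a + 1]
    return np.array([sum(int(o) * int(s) for o, s in zip(off, strides))
                     for off in offsets], dtype=np.int64)


def enumerate_moves_arrays(image: np.ndarray, labels: np.ndarray,
                           stats: RegionStats, p: EnergyParams,
                           conn: Optional[Connectivity] = None,
                           ps_maps: Optional[PSMaps] = None) -> MoveArrays:
    """All admissible candidate moves with energies and topology classes.

    A candidate relabels a pixel v to the label of one of its face
    neighbours (duplicates across neighbours collapse to one move whose
    source is the lexicographically smallest neighbour carrying the target
    label).  Forbidden moves (disallowed fusions) are pruned.
    """
    conn = conn or Connectivity.from_ndim(labels.ndim)
    shape = labels.shape
    face_offs = conn.fg_neighbors
    nb = neighbor_label_stack(labels, face_offs, fill=-1)
    flat_nb = nb.reshape(len(face_offs), -1)
    flat_lab = labels.ravel()

    v_parts, m_parts, dir_parts = [], [], []
    for k in range(len(face_offs)):
        cand = (flat_nb[k] != flat_lab) & (flat_nb[k] >= 0) & (flat_lab >= 0) & \
               ((flat_lab > 0) | (flat_nb[k] > 0))
        idx = np.nonzero(cand)[0]
        v_parts.append(idx)
        m_parts.append(flat_nb[k][idx].astype(np.int64))
        dir_parts.append(np.full(len(idx), k, dtype=np.int64))
    if not v_parts or sum(len(x) for x in v_parts) == 0:
        empty = np.empty(0, dtype=np.int64)
        return MoveArrays(shape, empty, empty.copy(), empty.copy(), empty.copy(),
                          np.empty(0), np.empty(0, dtype=np.int8),
                          np.empty(0, dtype=np.int8))
    v_all = np.concatenate(v_parts)
    m_all = np.concatenate(m_parts)
    d_all = np.concatenate(dir_parts)

    # dedupe (v, target) keeping the first direction in lexicographic offset
    # order: that source neighbour is the lexicographically smallest
    big = np.int64(max(int(labels.max()), 0) + 2)
    key = v_all * big + m_all
    _, first = np.unique(key, return_index=True)
    first.sort()
    v = v_all[first]
    l_to = m_all[first]
    d = d_all[first]
    off_flat = _flat_offsets(shape, face_offs)
    src = v + off_flat[d]
    l_from = flat_lab[v].astype(np.int64)

    order = np.lexsort((l_to, v))
    v, l_to, src, l_from = v[order], l_to[order], src[order], l_from[order]
    n = len(v)

    # face-neighbour labels gathered per move (out-of-grid = -1)
    nbv = flat_nb[:, v]

    # --- topology classification (vectorized) -----------------------------
    bg_offs = conn.bg_neighbors
    full_nb = neighbor_label_stack(labels, bg_offs, fill=0)
    nbv_full = full_nb.reshape(len(bg_offs), -1)[:, v].T.astype(np.int64)
    del full_nb

    kind = np.zeros(n, dtype=np.int8)
    ncomp = np.ones(n, dtype=np.int8)
    donors = l_from > 0
    if np.any(donors):
        t = batch_topological_numbers(nbv_full[donors], l_from[donors])
        nc = np.ones(n, dtype=np.int64)
        nc[donors] = np.maximum(t, 1)
        ncomp = np.minimum(nc, 127).astype(np.int8)
        kind[(ncomp > 1)] = K_SPLIT

    with np.errstate(divide="ignore", invalid="ignore"):
        means = np.where(stats.n > 0, stats.s / np.maximum(stats.n, 1), np.inf)
    fuse_any = np.zeros(n, dtype=bool)
    fuse_ok = np.ones(n, dtype=bool)
    grows_fg = l_to > 0
    for k in range(len(face_offs)):
        mk = nbv[k].astype(np.int64)
        rel = grows_fg & (mk > 0) & (mk != l_to)
        if not np.any(rel):
            continue
        fuse_any |= rel
        diff = np.abs(means[np.where(rel, l_to, 0)] - means[np.where(rel, mk, 0)])
        fuse_ok &= np.where(rel, diff <= p.theta, True)
    kind[fuse_any & fuse_ok] = K_FUSE
    kind[fuse_any & ~fuse_ok] = K_FORBIDDEN

    # --- energy differences ------------------------------------------------
    vals = image.ravel()[v]
    if p.model == "pc":
        de = pc_data_delta(stats, vals, l_from, l_to, p.noise)
    else:
        maps = ps_maps or PSMaps(image, labels, p.radius)
        de = np.empty(n, dtype=np.float64)
        for i in range(n):
            x = tuple(int(c) for c in np.unravel_index(v[i], shape))
            de[i] = ps_move_delta(image, labels, maps, x,
                                  int(l_from[i]), int(l_to[i]), p)
    if p.lam > 0:
        ingrid = nbv >= 0
        before = np.sum(ingrid & (nbv != l_from[None, :]), axis=0)
        after = np.sum(ingrid & (nbv != l_to[None, :]), axis=0)
        de = de + p.lam * (after - before)
    if p.alpha > 0:
        de = de + p.alpha * (kind == K_FUSE)

    keep = kind != K_FORBIDDEN
    return MoveArrays(shape, v[keep], src[keep], l_from[keep], l_to[keep],
                      de[keep], kind[keep], ncomp[keep])


def enumerate_moves(image, labels, stats: RegionStats, p: EnergyParams,
                    conn: Optional[Connectivity] = None) -> List[Move]:
    """Candidate moves as a list (forbidden moves pruned)."""
    img, lab = as_image(image), as_labels(labels)
    return enumerate_moves_arrays(img, lab, stats, p, conn).to_moves()


# ---------------------------------------------------------------------------
# dependency graph and selection
# ---------------------------------------------------------------------------

def _pixel_components(arrays: MoveArrays) -> np.ndarray:
    """Component id per move from the union of {target, source} pixel edges."""
    n = len(arrays)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    pixels = np.concatenate([arrays.v, arrays.src])
    uniq, inv = np.unique(pixels, return_inverse=True)
    iv, isrc = inv[:n], inv[n:]
    g = coo_matrix((np.ones(n, dtype=np.int8), (iv, isrc)),
                   shape=(len(uniq), len(uniq)))
    _, lab = connected_components(g, directed=False)
    comp_of_move = lab[iv]
    # renumber components by their smallest member pixel for determinism
    min_pix = np.full(lab.max() + 1, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(min_pix, lab, uniq)
    used = np.unique(comp_of_move)
    order = used[np.argsort(min_pix[used], kind="stable")]
    remap = np.empty(lab.max() + 1, dtype=np.int64)
    remap[order] = np.arange(len(order))
    return remap[comp_of_move]


def build_move_graph(moves, shape=None) -> MoveGraph:
    """Undirected causal-dependency graph, split into maximal connected
    sub-graphs (moves sharing any pixel are dependent)."""
    if isinstance(moves, MoveArrays):
        arrays = moves
    else:
        if shape is None:
            if not moves:
                arrays = MoveArrays((1, 1), *(np.empty(0, dtype=np.int64),) * 4,
                                    np.empty(0), np.empty(0, dtype=np.int8),
                                    np.empty(0, dtype=np.int8))
                return MoveGraph(arrays, np.empty(0, dtype=np.int64))
            shape = tuple(max(m.pixel[a] for m in moves) + 2
                          for a in range(len(moves[0].pixel)))
        arrays = MoveArrays.from_moves(moves, shape)
    return MoveGraph(arrays, _pixel_components(arrays))


def select_moves_idx(graph: MoveGraph, osc: Optional[OscillationState] = None
                     ) -> np.ndarray:
    """Indices of selected moves in deterministic execution order.

    Per sub-graph the move with the lowest energy difference wins (ties:
    lexicographic pixel, then target label); only moves with negative energy
    difference are candidates; across sub-graphs selections are ordered by
    (delta_e, pixel, target) and capped to the best
    ceil(acceptance_fraction * count).
    """
    a = graph.arrays
    neg = a.de < 0
    if osc is not None and osc.blacklist:
        for (v, lf, lt) in osc.blacklist:
            neg &= ~((a.v == v) & (a.l_from == lf) & (a.l_to == lt))
    if not np.any(neg):
        return np.empty(0, dtype=np.int64)
    idx = np.nonzero(neg)[0]
    comp = graph.comp[idx]
    order = np.lexsort((a.l_to[idx], a.v[idx], a.de[idx], comp))
    sidx = idx[order]
    scomp = comp[order]
    _, firsts = np.unique(scomp, return_index=True)
    chosen = sidx[firsts]
    final = chosen[np.lexsort((a.l_to[chosen], a.v[chosen], a.de[chosen]))]
    frac = osc.acceptance_fraction if osc is not None else 1.0
    if frac < 1.0:
        keep = max(int(math.ceil(frac * len(final))), 1) if len(final) else 0
        final = final[:keep]
    return final


def select_moves(graph: MoveGraph, osc: Optional[OscillationState] = None
                 ) -> List[Move]:
    """Selected moves as a list, in deterministic execution order."""
    idx = select_moves_idx(graph, osc)
    all_moves = graph.arrays.to_moves()
    return [all_moves[i] for i in idx]


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

class FreshLabels:
    """Deterministic allocator of globally unique fresh labels.

    Rank r of P draws base + 1 + r + k*P for k = 0, 1, ...; a single rank
    draws base+1, base+2, ... which matches the sequential driver.
    """

    def __init__(self, base: int, rank: int = 0, stride: int = 1):
        self.base = int(base)
        self.rank = int(rank)
        self.stride = int(stride)
        self.k = 0

    def next(self) -> int:
        lab = self.base + 1 + self.rank + self.k * self.stride
        self.k += 1
        return lab


@dataclass
class ExecResult:
    accepted: List[Tuple[int, int, int]]       # (flat pixel, l_from, l_to)
    relabel_events: List[Tuple[int, int]]      # (old label, new label)
    n_accepted: int
    dropped: int = 0


def _face_neighbor_info(labels: np.ndarray, x: Pixel):
    labs = []
    for ax in range(labels.ndim):
        for dlt in (-1, 1):
            y = list(x)
            y[ax] += dlt
            if 0 <= y[ax] < labels.shape[ax]:
                labs.append(int(labels[tuple(y)]))
    return labs


def execute_moves(image: np.ndarray, labels: np.ndarray, stats: RegionStats,
                  arrays: MoveArrays, order_idx: np.ndarray, p: EnergyParams,
                  conn: Connectivity, alloc: FreshLabels) -> ExecResult:
    """Execute selected moves in order with per-move re-validation.

    Topology is re-checked against the current state: moves invalidated by
    earlier executed moves are dropped.  Fusions relabel the higher label to
    the lower immediately; splits are confirmed by flood fill after all
    moves and the detached components receive fresh labels (the component
    containing the lexicographically smallest pixel keeps the old label).
    """
    from .topology import topological_number

    accepted: List[Tuple[int, int, int]] = []
    events: List[Tuple[int, int]] = []
    split_check: Set[int] = set()
    dropped = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pass

    for i in order_idx:
        v = int(arrays.v[i])
        l_from = int(arrays.l_from[i])
        l_to = int(arrays.l_to[i])
        x = tuple(int(c) for c in np.unravel_index(v, labels.shape))
        if int(labels[x]) != l_from:
            dropped += 1
            continue
        nb_labs = _face_neighbor_info(labels, x)
        if l_to != 0 and l_to not in nb_labs:
            dropped += 1
            continue
        # fusion admissibility against live statistics
        fuse_with = sorted({m for m in nb_labs if m > 0 and m != l_to}) \
            if l_to > 0 else []
        if fuse_with:
            mu_to = stats.s[l_to] / stats.n[l_to] if stats.n[l_to] > 0 else np.inf
            ok = True
            for m in fuse_with:
                if stats.n[m] == 0:
                    ok = False
                    break
                if abs(mu_to - stats.s[m] / stats.n[m]) > p.theta:
                    ok = False
                    break
            if not ok:
                dropped += 1
                continue
        if l_from > 0 and stats.n[l_from] > 1:
            if topological_number(labels, x, l_from, conn) > 1:
                split_check.add(l_from)
        labels[x] = l_to
        stats.move_pixel(float(image[x]), l_from, l_to)
        accepted.append((v, l_from, l_to))
        if fuse_with:
            group = sorted(set(fuse_with) | {l_to})
            target = group[0]
            for h in group[1:]:
                labels[labels == h] = target
                stats.merge(target, h)
                events.append((h, target))
                split_check.discard(h)

    # confirm splits by flood fill; detached components get fresh labels
    st = face_structure(labels.ndim)
    for donor in sorted(split_check):
        if donor >= len(stats.n) or stats.n[donor] == 0:
            continue
        mask = labels == donor
        comp, ncmp = ndimage.label(mask, structure=st)
        for c in range(2, ncmp + 1):
            new = alloc.next()
            sel = comp == c
            labels[sel] = new
            stats.transfer(image[sel], donor, new)
            events.append((donor, new))

    return ExecResult(accepted, events, len(accepted), dropped)


# ---------------------------------------------------------------------------
# oscillation damping
# ---------------------------------------------------------------------------

def detect_oscillation(osc: OscillationState,
                       new_acceptances: Sequence[Tuple[int, int, int]],
                       energy_trace: Optional[Sequence[float]] = None
                       ) -> OscillationState:
    """Update the damping state after an iteration.

    Flags when an acceptance exactly reverses one from the last W
    iterations, or when the total energy failed to decrease over W
    iterations; on a flag the acceptance fraction halves (floor f_min).
    """
    new_set = {(int(v), int(a), int(b)) for v, a, b in new_acceptances}
    for key in new_set:
        osc.exec_counts[key] = osc.exec_counts.get(key, 0) + 1
        v, a, b = key
        rev = (v, b, a)
        if (osc.exec_counts[key] >= osc.blacklist_after and
                osc.exec_counts.get(rev, 0) >= osc.blacklist_after):
            osc.blacklist.add(key)
            osc.blacklist.add(rev)
    flagged = False
    recent: Set[Tuple[int, int, int]] = set()
    for s in osc.window[-osc.window_size:]:
        recent |= s
    for v, a, b in new_set:
        if (v, b, a) in recent:
            flagged = True
            break
    if not flagged and energy_trace is not None:
        tr = list(energy_trace)
        w = osc.window_size
        if len(tr) > w and tr[-1] >= tr[-1 - w]:
            flagged = True
    if flagged:
        osc.acceptance_fraction = max(osc.acceptance_fraction / 2.0, osc.f_min)
    osc.flagged = flagged
    osc.window.append(new_set)
    if len(osc.window) > osc.window_size + 1:
        osc.window.pop(0)
    return osc


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def state_energy(image: np.ndarray, labels: np.ndarray, stats: RegionStats,
                 p: EnergyParams, ps_maps: Optional[PSMaps] = None) -> float:
    return total_energy(image, labels, p, stats=stats, ps_maps=ps_maps)


def step(image, labels, stats: RegionStats, p: EnergyParams,
         osc: OscillationState, conn: Optional[Connectivity] = None,
         alloc: Optional[FreshLabels] = None,
         ps_maps: Optional[PSMaps] = None):
    """One sequential iteration, mutating labels and stats in place.

    Returns (labels, stats, energy_after, n_accepted).
    """
    img, lab = as_image(image), as_labels(labels)
    conn = conn or Connectivity.from_ndim(lab.ndim)
    alloc = alloc or FreshLabels(int(lab.max()))
    maps = ps_maps
    if p.model == "ps" and maps is None:
        maps = PSMaps(img, lab, p.radius)
    arrays = enumerate_moves_arrays(img, lab, stats, p, conn, maps)
    graph = MoveGraph(arrays, _pixel_components(arrays))
    sel = select_moves_idx(graph, osc)
    res = execute_moves(img, lab, stats, arrays, sel, p, conn, alloc)
    # refresh the statistics from the fields: incremental updates carry
    # last-bit rounding that would otherwise drift from the distributed
    # runtime's per-iteration reduction
    if res.n_accepted:
        stats = RegionStats.from_fields(img, lab)
    new_maps = PSMaps(img, lab, p.radius) if p.model == "ps" else None
    e = state_energy(img, lab, stats, p, new_maps)
    return lab, stats, e, res.n_accepted, res, new_maps


@dataclass
class SegResult:
    labels: np.ndarray
    trace: EnergyTrace
    converged: bool
    iterations: int


def run_sequential(image, init_labels, p: EnergyParams, max_iter: int = 1000,
                   conn: Optional[Connectivity] = None,
                   osc: Optional[OscillationState] = None) -> SegResult:
    """Iterate to convergence (no accepted move) or ``max_iter``.

    The initial labeling is normalized to face-connected components of its
    FG mask, which both enforces the label-field invariants and matches the
    distributed label initialization for a single rank.
    """
    img = as_image(image)
    lab = normalize_labels(as_labels(init_labels))
    if img.shape != lab.shape:
        raise ValueError("image and label field shapes differ")
    conn = conn or Connectivity.from_ndim(lab.ndim)
    stats = RegionStats.from_fields(img, lab)
    osc = osc or OscillationState()
    alloc = FreshLabels(int(lab.max()))
    maps = PSMaps(img, lab, p.radius) if p.model == "ps" else None
    trace = EnergyTrace()
    trace.append(state_energy(img, lab, stats, p, maps))
    converged = False
    it = 0
    while it < max_iter:
        lab, stats, e, n_acc, res, maps = step(img, lab, stats, p, osc, conn,
                                               alloc, maps)
        if n_acc == 0:
            converged = True
            break
        it += 1
        trace.append(e)
        detect_oscillation(osc, res.accepted, trace.energies)
    return SegResult(lab, trace, converged, it)
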