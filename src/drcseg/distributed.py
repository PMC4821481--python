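"""Distributed region competition on a deterministic simulated runtime.

The global segmentation problem is solved collectively by P ranks, each
holding one block of the image plus ghost layers.  Three distributed
algorithms operate on top of the sequential move machinery:

* global label initialization by per-rank component labeling followed by
  iterative min-label relaxation across block boundaries;
* checkerboard contour propagation: black ranks resolve their boundary
  move sub-graphs first and ship the decisions to white neighbours, which
  accept them verbatim and fill in only compatible moves of their own;
* hot-particle region re-labeling: label changes at block boundaries
  activate boundary particles which seed flood fills on the receiving
  rank, iterating (with a global reduction) until no rank is hot.

Communication is simulated by per-round message queues: delivery happens
only at round boundaries, so the order in which ranks execute within a
round cannot affect any observable output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage

from .core import (LABEL_DTYPE, Connectivity, RegionStats, as_image,
                   as_labels, face_structure, perimeter_pairs)
from .energy import (EnergyParams, EnergyTrace, PSMaps, _cost_gaussian,
                     _cost_poisson, ps_energy_over)
from .optimizer import (ExecResult, FreshLabels, MoveArrays, MoveGraph,
                        OscillationState, _pixel_components,
                        detect_oscillation, enumerate_moves_arrays,
                        execute_moves, select_moves_idx)
from .decomposition import (BLACK, WHITE, DomainGrid, SubDomainState,
                            decompose, exchange_ghosts, gather, ghost_width,
                            make_states)


# ---------------------------------------------------------------------------
# runtime
# ---------------------------------------------------------------------------

@dataclass
class RunStats:
    """Per-iteration bookkeeping of the distributed run."""

    energy: List[float] = field(default_factory=list)
    accepted: List[int] = field(default_factory=list)
    messages: List[int] = field(default_factory=list)
    hot_particles: List[int] = field(default_factory=list)
    relabel_rounds: List[int] = field(default_factory=list)
    init_rounds: int = 0

    def to_dataframe(self):
        import pandas as pd
        n = len(self.accepted)
        return pd.DataFrame({
            "iteration": np.arange(1, n + 1),
            "energy": self.energy[1:n + 1] if len(self.energy) > n else self.energy[:n],
            "accepted_moves": self.accepted,
            "messages": self.messages,
            "hot_particles": self.hot_particles,
            "relabel_rounds": self.relabel_rounds,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class SimRuntime:
    """Deterministic round-based stand-in for a message-passing machine.

    Holds one ``SubDomainState`` per rank.  ``order`` is the rank execution
    permutation within each phase; shuffling it must leave every observable
    output bit-identical (asserted in tests).
    """

    def __init__(self, image, init_labels, p: EnergyParams,
                 dims: Sequence[int], g: Optional[int] = None,
                 conn: Optional[Connectivity] = None,
                 order: Optional[Sequence[int]] = None):
        self.image = as_image(image)
        init = as_labels(init_labels)
        if self.image.shape != init.shape:
            raise ValueError("image and label field shapes differ")
        self.p = p
        self.conn = conn or Connectivity.from_ndim(self.image.ndim)
        if g is None:
            g = ghost_width(p)
        pad = g
        if p.model == "ps":
            # exact PS energy differences for owned pixels need label data
            # up to 2R+1 away; widen the stored frame (not the nominal
            # ghost width) accordingly
            pad = max(g, 2 * p.radius + 1)
        if int(np.prod(dims)) == 1:
            g = pad = 0  # a single rank owns the whole image; no frame needed
        self.grid = decompose(self.image.shape, dims, g)
        self.states = make_states(self.image, init, self.grid, pad=pad)
        self.order = list(order) if order is not None else list(range(self.grid.n_ranks))
        self.round_no = 0
        self.stats_global: Optional[RegionStats] = None
        self.alloc_base = 0
        self.osc = [OscillationState() for _ in range(self.grid.n_ranks)]
        self.trace = EnergyTrace()
        self.runstats = RunStats()
        self.scratch: Dict[int, dict] = {}

    # -- collectives --------------------------------------------------------

    def allreduce_stats(self) -> RegionStats:
        size = 1
        parts = []
        for s in self.states:
            flat = s.labels_loc[s.owned].ravel()
            vals = s.image_loc[s.owned].ravel()
            m = int(flat.max(initial=0))
            size = max(size, m + 1)
            n = np.bincount(flat, minlength=m + 1).astype(np.int64)
            sm = np.bincount(flat, weights=vals, minlength=m + 1)
            q = np.bincount(flat, weights=vals * vals, minlength=m + 1)
            parts.append((n, sm, q))
        st = RegionStats(size - 1)
        for n, sm, q in parts:
            st.n[:len(n)] += n
            st.s[:len(sm)] += sm
            st.q[:len(q)] += q
        return st

    def global_energy(self, stats: RegionStats) -> float:
        p = self.p
        pairs = 0
        for s in self.states:
            pairs += _rank_perimeter(s, self.grid)
        if p.model == "pc":
            live = np.nonzero(stats.n)[0]
            if p.noise == "gaussian":
                data = float(np.sum(_cost_gaussian(stats.n[live], stats.s[live],
                                                   stats.q[live])))
            else:
                data = float(np.sum(_cost_poisson(stats.n[live], stats.s[live])))
        else:
            data = 0.0
            for s in self.states:
                maps = self.scratch.get(s.rank, {}).get("maps_post")
                if maps is None:
                    maps = PSMaps(s.image_loc, s.labels_loc, p.radius)
                owned = np.zeros(s.labels_loc.shape, dtype=bool)
                owned[s.owned] = True
                data += ps_energy_over(s.image_loc, s.labels_loc, p, maps, owned)
        return data + p.lam * pairs

    def gather_labels(self) -> np.ndarray:
        return gather(self.states, self.grid, "labels")


def _rank_perimeter(s: SubDomainState, grid: DomainGrid) -> int:
    """Differing face pairs among owned pixels plus positive-direction
    cross-boundary pairs (each global pair counted by the rank owning its
    lexicographically smaller pixel)."""
    own = s.labels_loc[s.owned]
    total = perimeter_pairs(own)
    for ax in range(own.ndim):
        if s.block[ax].stop < grid.shape[ax]:
            idx_a = [slice(None)] * own.ndim
            idx_a[ax] = slice(own.shape[ax] - 1, own.shape[ax])
            a = own[tuple(idx_a)]
            idx_b = list(s.owned)
            idx_b[ax] = slice(s.owned[ax].stop, s.owned[ax].stop + 1)
            b = s.labels_loc[tuple(idx_b)]
            total += int(np.count_nonzero(a != b))
    return total


# ---------------------------------------------------------------------------
# global label initialization (min-label relaxation)
# ---------------------------------------------------------------------------

def initial_global_labels(rt: SimRuntime) -> SimRuntime:
    """Globally unique component labels from conflicting per-rank labelings.

    Phase 1: rank r labels its local face-connected FG components with
    r + 1 + k*P (k-th component in raster order), so no label is used
    twice.  Phase 2: boundary labels are iteratively replaced by the
    minimum across each block face until a global fixed point; each global
    component ends up with the minimum label it ever held.
    """
    P = rt.grid.n_ranks
    st = face_structure(rt.image.ndim)
    for r in rt.order:
        s = rt.states[r]
        own = s.labels_loc[s.owned]
        comp, n = ndimage.label(own > 0, structure=st)
        lut = np.zeros(n + 1, dtype=np.int64)
        lut[1:] = s.rank + 1 + np.arange(n, dtype=np.int64) * P
        s.labels_loc[s.owned] = lut[comp]
        # wipe stale in-image ghosts before the first exchange; cells
        # beyond the image boundary keep the -1 sentinel
        mask = np.ones(s.labels_loc.shape, dtype=bool)
        mask[s.owned] = False
        s.labels_loc[mask] = 0
        s.labels_loc[s.out_of_image_mask(rt.grid.shape)] = -1

    rounds = 0
    limit = 4 * P + 16
    while True:
        exchange_ghosts(rt.states, rt.grid, "labels")
        changed_any = False
        for r in rt.order:
            if _relax_min_once(rt.states[r]):
                changed_any = True
        if not changed_any:
            break
        rounds += 1
        if rounds > limit:
            raise RuntimeError("label relaxation failed to reach a fixed point")
    rt.runstats.init_rounds = rounds
    return rt


def _relax_min_once(s: SubDomainState) -> bool:
    """Lower owned labels to the minimum over face-adjacent ghost labels."""
    if s.g == 0:
        return False
    own = s.labels_loc[s.owned]
    mapping: Dict[int, int] = {}
    for ax in range(own.ndim):
        for side in (0, 1):
            edge = [slice(None)] * own.ndim
            ghost = list(s.owned)
            if side == 0:
                edge[ax] = slice(0, 1)
                ghost[ax] = slice(s.owned[ax].start - 1, s.owned[ax].start)
            else:
                edge[ax] = slice(own.shape[ax] - 1, own.shape[ax])
                ghost[ax] = slice(s.owned[ax].stop, s.owned[ax].stop + 1)
            a = own[tuple(edge)].ravel()
            b = s.labels_loc[tuple(ghost)].ravel()
            both = (a > 0) & (b > 0) & (b < a)
            for la, lb in zip(a[both], b[both]):
                la, lb = int(la), int(lb)
                cur = mapping.get(la, la)
                if lb < cur:
                    mapping[la] = lb
    if not mapping:
        return False
    uniq = np.unique(own)
    lut_src = uniq
    lut_dst = np.array([mapping.get(int(u), int(u)) for u in uniq],
                       dtype=own.dtype)
    idx = np.searchsorted(lut_src, own)
    s.labels_loc[s.owned] = lut_dst[idx]
    return True


# ---------------------------------------------------------------------------
# sub-graph partitioning
# ---------------------------------------------------------------------------

@dataclass
class SubGraphPartition:
    """Interior vs boundary classification of a rank's move sub-graphs."""

    interior: List[int]
    boundary: List[int]
    is_boundary: np.ndarray  # per component id


def partition_subgraphs(graph: MoveGraph, s: SubDomainState) -> SubGraphPartition:
    """A maximal connected sub-graph is boundary iff any of its moves
    touches a pixel outside the rank's owned block."""
    a = graph.arrays
    ncomp = graph.n_components
    is_b = np.zeros(ncomp, dtype=bool)
    if len(a) and ncomp:
        inside = _inside_owned(a.v, s) & _inside_owned(a.src, s)
        np.logical_or.at(is_b, graph.comp, ~inside)
    interior = [c for c in range(ncomp) if not is_b[c]]
    boundary = [c for c in range(ncomp) if is_b[c]]
    return SubGraphPartition(interior, boundary, is_b)


def _inside_owned(flat_local: np.ndarray, s: SubDomainState) -> np.ndarray:
    shape = s.labels_loc.shape
    coords = np.unravel_index(flat_local, shape)
    ok = np.ones(len(flat_local), dtype=bool)
    for ax, c in enumerate(coords):
        ok &= (c >= s.owned[ax].start) & (c < s.owned[ax].stop)
    return ok


def _local_to_global_flat(flat_local: np.ndarray, s: SubDomainState,
                          shape: Tuple[int, ...]) -> np.ndarray:
    coords = np.unravel_index(flat_local, s.labels_loc.shape)
    gcoords = [c + o for c, o in zip(coords, s.origin)]
    return np.ravel_multi_index(gcoords, shape)


def _global_to_local_flat(flat_global: int, s: SubDomainState,
                          shape: Tuple[int, ...]) -> int:
    coords = np.unravel_index(flat_global, shape)
    lcoords = tuple(int(c) - o for c, o in zip(coords, s.origin))
    return int(np.ravel_multi_index(lcoords, s.labels_loc.shape))


def _owner_rank(flat_global: int, grid: DomainGrid) -> int:
    coords = np.unravel_index(flat_global, grid.shape)
    gc = []
    for ext, d, c in zip(grid.shape, grid.dims, coords):
        base = ext // d
        gc.append(min(int(c) // base, d - 1))
    return grid.rank_of(tuple(gc))


# ---------------------------------------------------------------------------
# contour propagation (checkerboard black/white resolution)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Decision:
    """A move decision shipped between ranks (global pixel coordinates)."""

    v: int        # global flat pixel
    src: int      # global flat source pixel
    l_from: int
    l_to: int
    de: float
    sender: int


def _enumerate_local(rt: SimRuntime, s: SubDomainState) -> Tuple[MoveArrays, np.ndarray]:
    """Enumerate candidate moves on the local view and keep only pixels
    whose full topology neighbourhood is available and that lie inside the
    image."""
    maps = None
    if rt.p.model == "ps":
        maps = PSMaps(s.image_loc, s.labels_loc, rt.p.radius)
        rt.scratch.setdefault(s.rank, {})["maps_pre"] = maps
    arrays = enumerate_moves_arrays(s.image_loc, s.labels_loc,
                                    rt.stats_global_copy(s.rank), rt.p,
                                    rt.conn, maps)
    if len(arrays) == 0:
        return arrays, np.empty(0, dtype=np.int64)
    shape_loc = s.labels_loc.shape
    coords = np.unravel_index(arrays.v, shape_loc)
    keep = np.ones(len(arrays), dtype=bool)
    for ax, c in enumerate(coords):
        gc = c + s.origin[ax]
        keep &= (gc >= 0) & (gc < rt.grid.shape[ax])
        # a view-edge pixel is only admissible where the view edge is the
        # image border (its out-of-view neighbours are true background)
        keep &= (c > 0) | (gc == 0)
        keep &= (c < shape_loc[ax] - 1) | (gc == rt.grid.shape[ax] - 1)
    sel = np.nonzero(keep)[0]
    arrays = MoveArrays(shape_loc, arrays.v[sel], arrays.src[sel],
                        arrays.l_from[sel], arrays.l_to[sel], arrays.de[sel],
                        arrays.kind[sel], arrays.ncomp[sel])
    return arrays, sel


def contour_propagation_step(rt: SimRuntime) -> Dict[int, List[Decision]]:
    """One checkerboard move-selection and execution round.

    Returns the per-rank executed decisions.  Requires fresh ghosts and a
    current global statistics reduction (``rt.stats_global``).
    """
    grid, p = rt.grid, rt.p
    messages = 0

    # --- local enumeration, graphs, partition -----------------------------
    for r in rt.order:
        s = rt.states[r]
        arrays, _ = _enumerate_local(rt, s)
        graph = MoveGraph(arrays, _pixel_components(arrays))
        part = partition_subgraphs(graph, s)
        sc = rt.scratch.setdefault(r, {})
        sc["arrays"], sc["graph"], sc["part"] = arrays, graph, part
        sc["own_sel"] = []
        sc["received"] = []
        sc["v_glob"] = (_local_to_global_flat(arrays.v, s, grid.shape)
                        if len(arrays) else np.empty(0, dtype=np.int64))
        sc["src_glob"] = (_local_to_global_flat(arrays.src, s, grid.shape)
                          if len(arrays) else np.empty(0, dtype=np.int64))

    # --- black ranks: boundary sub-graphs first ---------------------------
    outboxes: Dict[int, List[Decision]] = {r: [] for r in range(grid.n_ranks)}
    for r in rt.order:
        s = rt.states[r]
        if s.color != BLACK:
            continue
        sc = rt.scratch[r]
        sel = _select_boundary_black(rt, s, sc)
        sc["own_sel"].extend(sel)
        for d in sel:
            for nb in grid.neighbors(r):
                if rt.states[nb].color == WHITE:
                    outboxes[nb].append(d)
    for r in rt.order:
        if outboxes[r]:
            senders = {d.sender for d in outboxes[r]}
            messages += len(senders)
        # two diagonal black ranks may decide the same corner pixel from
        # their truncated views; resolve deterministically (best move wins)
        by_v: Dict[int, Decision] = {}
        for d in sorted(outboxes[r], key=lambda d: (d.v, d.de, d.l_to, d.sender)):
            by_v.setdefault(d.v, d)
        rt.scratch[r]["received"] = sorted(by_v.values(),
                                           key=lambda d: (d.de, d.v, d.l_to))

    # --- white ranks: boundary under received constraints; everyone:
    #     interior sub-graphs ----------------------------------------------
    for r in rt.order:
        s = rt.states[r]
        sc = rt.scratch[r]
        if s.color == WHITE:
            sc["own_sel"].extend(_select_boundary_white(rt, s, sc))
        sc["own_sel"].extend(_select_interior(rt, s, sc))

    # --- per-rank damping cap, then route to owners ------------------------
    exec_in: Dict[int, List[Decision]] = {r: [] for r in range(grid.n_ranks)}
    for r in rt.order:
        sc = rt.scratch[r]
        own = sorted(sc["own_sel"], key=lambda d: (d.de, d.v, d.l_to))
        frac = rt.osc[r].acceptance_fraction
        if frac < 1.0 and own:
            own = own[:max(int(math.ceil(frac * len(own))), 1)]
        sc["own_sel"] = own
        for d in own:
            owner = _owner_rank(d.v, grid)
            exec_in[owner].append(d)
            if owner != r:
                messages += 1
    # received black decisions on white-owned pixels execute verbatim
    for r in rt.order:
        s = rt.states[r]
        for d in rt.scratch[r]["received"]:
            if _owner_rank(d.v, grid) == r:
                exec_in[r].append(d)

    # --- execution by pixel owner ------------------------------------------
    executed: Dict[int, List[Decision]] = {}
    n_accepted_total = 0
    for r in rt.order:
        s = rt.states[r]
        sc = rt.scratch[r]
        dec = exec_in[r]
        # drop duplicates (a black decision also kept by its selector)
        seen = set()
        uniq: List[Decision] = []
        for d in sorted(dec, key=lambda d: (d.de, d.v, d.l_to)):
            key = (d.v, d.l_from, d.l_to)
            if key in seen or key in rt.osc[r].blacklist:
                continue
            seen.add(key)
            uniq.append(d)
        alloc = FreshLabels(rt.alloc_base, rank=r, stride=grid.n_ranks)
        sc["shell_pre"] = s.labels_loc[s.owned].copy()
        if uniq:
            vloc = np.array([_global_to_local_flat(d.v, s, grid.shape)
                             for d in uniq], dtype=np.int64)
            arr = MoveArrays(s.labels_loc.shape, vloc, vloc.copy(),
                             np.array([d.l_from for d in uniq], dtype=np.int64),
                             np.array([d.l_to for d in uniq], dtype=np.int64),
                             np.array([d.de for d in uniq]),
                             np.zeros(len(uniq), dtype=np.int8),
                             np.ones(len(uniq), dtype=np.int8))
            stats = rt.stats_global_copy(r)
            res = execute_moves(s.image_loc, s.labels_loc, stats, arr,
                                np.arange(len(uniq)), p, rt.conn, alloc)
        else:
            res = ExecResult([], [], 0)
        sc["exec"] = res
        sc["alloc_high"] = alloc.base + alloc.k * alloc.stride
        executed[r] = uniq
        n_accepted_total += res.n_accepted

    rt.scratch["_messages"] = rt.scratch.get("_messages", 0) + messages
    rt.scratch["_accepted"] = n_accepted_total
    return executed


def _candidate_decisions(rt, s, sc, comp_id) -> List[Decision]:
    a = sc["arrays"]
    idx = np.nonzero((sc["graph"].comp == comp_id) & (a.de < 0))[0]
    bl = rt.osc[s.rank].blacklist
    out = []
    for i in idx:
        key = (int(sc["v_glob"][i]), int(a.l_from[i]), int(a.l_to[i]))
        if key in bl:
            continue
        out.append(Decision(key[0], int(sc["src_glob"][i]),
                            key[1], key[2], float(a.de[i]), s.rank))
    return out


def _best(decisions: List[Decision]) -> Optional[Decision]:
    if not decisions:
        return None
    return min(decisions, key=lambda d: (d.de, d.v, d.l_to))


def _select_boundary_black(rt, s, sc) -> List[Decision]:
    """Black rank: best move per boundary sub-graph.

    Selections are restricted to pixels owned by this rank or by white
    face neighbours (pixels owned by diagonal, same-colored ranks are left
    to their owners)."""
    grid = rt.grid
    white_faces = {nb for nb in grid.neighbors(s.rank)
                   if rt.states[nb].color == WHITE
                   and sum(abs(a - b) for a, b in
                           zip(grid.coords_of(nb), s.coords)) == 1}
    allowed = white_faces | {s.rank}
    out = []
    a = sc["arrays"]
    for c in sc["part"].boundary:
        # skip sub-graphs with no owned pixel: they belong to a neighbour
        # and are fully visible there
        idx = np.nonzero(sc["graph"].comp == c)[0]
        comp_pixels = [int(sc["v_glob"][i]) for i in idx] + \
                      [int(sc["src_glob"][i]) for i in idx]
        if not any(_owner_rank(px, grid) == s.rank for px in comp_pixels):
            continue
        cands = [d for d in _candidate_decisions(rt, s, sc, c)
                 if _owner_rank(d.v, grid) in allowed]
        b = _best(cands)
        if b is not None:
            out.append(b)
    return out


def _select_boundary_white(rt, s, sc) -> List[Decision]:
    """White rank: skip sub-graphs already resolved by a received black
    decision; otherwise pick the best own-pixel move that does not conflict
    with any received decision (sharing a pixel of the decision's move or
    its face neighbourhood)."""
    grid = rt.grid
    received = sc["received"]
    blocked: Set[int] = set()
    resolved_pixels: Set[int] = set()
    for d in received:
        resolved_pixels |= {d.v, d.src}
        blocked |= {d.v, d.src} | set(_face_flat_neighbors(d.v, grid.shape))
    out = []
    for c in sc["part"].boundary:
        cands = _candidate_decisions(rt, s, sc, c)
        comp_pixels = {x for d in cands for x in (d.v, d.src)}
        a = sc["arrays"]
        idx = np.nonzero(sc["graph"].comp == c)[0]
        comp_pixels |= {int(sc["v_glob"][i]) for i in idx}
        comp_pixels |= {int(sc["src_glob"][i]) for i in idx}
        if comp_pixels & resolved_pixels:
            continue  # black already decided in this sub-graph
        cands = [d for d in cands
                 if _owner_rank(d.v, grid) == s.rank
                 and not ({d.v, d.src} & blocked)]
        b = _best(cands)
        if b is not None:
            out.append(b)
    return out


def _select_interior(rt, s, sc) -> List[Decision]:
    out = []
    for c in sc["part"].interior:
        b = _best(_candidate_decisions(rt, s, sc, c))
        if b is not None:
            out.append(b)
    return out


def _face_flat_neighbors(flat: int, shape) -> List[int]:
    coords = list(np.unravel_index(flat, shape))
    out = []
    for ax in range(len(shape)):
        for d in (-1, 1):
            c = coords.copy()
            c[ax] += d
            if 0 <= c[ax] < shape[ax]:
                out.append(int(np.ravel_multi_index(c, shape)))
    return out


# ---------------------------------------------------------------------------
# hot-particle region re-labeling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HotParticle:
    pixel: int       # global flat
    old: int
    new: int
    sender: int


def _compose_events(events: Sequence[Tuple[int, int]]) -> Dict[int, Set[int]]:
    """Labels reachable from each source label through an ordered sequence
    of (old -> new) relabel events.

    A split maps one old label to several new ones (one per detached
    component), so the result is a set-valued reachability map, not a
    function.
    """
    reach: Dict[int, Set[int]] = {}
    for old, new in events:
        for targets in reach.values():
            if old in targets:
                targets.add(new)
        reach.setdefault(old, set()).add(new)
    return reach


def _shell_events(s: SubDomainState, pre: np.ndarray, grid: DomainGrid,
                  event_map: Dict[int, Set[int]],
                  suppress: Optional[Set[Tuple[int, int, int]]] = None
                  ) -> List[HotParticle]:
    """Hot particles for owned boundary-shell pixels whose label was
    rewritten by a region-relabel event (fusion or split).

    Ordinary single-pixel moves are not hot: they reach the neighbours
    through the regular ghost exchange.  ``suppress`` holds
    (neighbor_rank, old, new) triples that must not be re-sent (the change
    was received from that rank in this round)."""
    if not event_map:
        return []
    post = s.labels_loc[s.owned]
    changed = np.argwhere(post != pre)
    out = []
    shape = grid.shape
    for c in changed:
        old, new = int(pre[tuple(c)]), int(post[tuple(c)])
        if old <= 0 or new not in event_map.get(old, ()):
            continue
        faces = []
        for ax in range(post.ndim):
            if c[ax] == 0 and s.block[ax].start > 0:
                faces.append((ax, -1))
            if c[ax] == post.shape[ax] - 1 and s.block[ax].stop < shape[ax]:
                faces.append((ax, 1))
        if not faces:
            continue
        gco = tuple(int(v) + b.start for v, b in zip(c, s.block))
        gflat = int(np.ravel_multi_index(gco, shape))
        for ax, d in faces:
            nb_coords = list(s.coords)
            nb_coords[ax] += d
            nb = grid.rank_of(tuple(nb_coords))
            if suppress and (nb, old, new) in suppress:
                continue
            out.append(HotParticle(gflat, old, new, s.rank))
    return out


def relabel_regions(rt: SimRuntime) -> SimRuntime:
    """Algorithm: hot-particle distributed re-labeling to a global fixpoint.

    Boundary particles whose label changed become hot and are exchanged;
    received hot ghosts seed local flood fills (labels are matched exactly
    against the sender's previous value, with lower labels always winning
    a region's identity), iterating with a global reduction on the hot
    flag until no rank is hot.  Regions without label changes are never
    touched and generate no traffic.
    """
    grid = rt.grid
    st = face_structure(rt.image.ndim)
    hot_out: Dict[int, List[HotParticle]] = {}
    for r in rt.order:
        s = rt.states[r]
        pre = rt.scratch[r]["shell_pre"]
        emap = _compose_events(rt.scratch[r]["exec"].relabel_events)
        hot_out[r] = _shell_events(s, pre, grid, emap)
        s.hotpart = bool(hot_out[r])

    rounds = 0
    n_hot_total = 0
    limit = 8 * grid.n_ranks + 32
    while any(s.hotpart for s in rt.states):  # global reduce on hotpart
        rounds += 1
        if rounds > limit:
            raise RuntimeError("hot-particle re-labeling failed to terminate")
        inbox: Dict[int, List[HotParticle]] = {r: [] for r in range(grid.n_ranks)}
        for r in rt.order:
            for hp in hot_out[r]:
                owner_faces = _hot_targets(hp, rt.states[r], grid)
                for nb in owner_faces:
                    inbox[nb].append(hp)
                    n_hot_total += 1
            hot_out[r] = []
        for r in rt.order:
            s = rt.states[r]
            events = sorted(inbox[r], key=lambda h: (h.pixel, h.old, h.new))
            suppress: Set[Tuple[int, int, int]] = set()
            pre = s.labels_loc[s.owned].copy()
            for hp in events:
                _apply_hot(s, hp, grid, st)
                suppress.add((hp.sender, hp.old, hp.new))
            emap = _compose_events([(h.old, h.new) for h in events])
            hot_out[r] = _shell_events(s, pre, grid, emap, suppress)
            s.hotpart = bool(hot_out[r])

    rt.scratch["_hot"] = n_hot_total
    rt.scratch["_rounds"] = rounds
    return rt


def _hot_targets(hp: HotParticle, s: SubDomainState, grid: DomainGrid) -> List[int]:
    coords = np.unravel_index(hp.pixel, grid.shape)
    out = []
    for ax in range(len(grid.shape)):
        for d in (-1, 1):
            if (d == -1 and coords[ax] == s.block[ax].start and
                    s.block[ax].start > 0):
                nb = list(s.coords)
                nb[ax] -= 1
                out.append(grid.rank_of(tuple(nb)))
            if (d == 1 and coords[ax] == s.block[ax].stop - 1 and
                    s.block[ax].stop < grid.shape[ax]):
                nb = list(s.coords)
                nb[ax] += 1
                out.append(grid.rank_of(tuple(nb)))
    return out


def _apply_hot(s: SubDomainState, hp: HotParticle, grid: DomainGrid,
               st: np.ndarray) -> None:
    coords = np.unravel_index(hp.pixel, grid.shape)
    loc = tuple(int(c) - o for c, o in zip(coords, s.origin))
    if any(not (0 <= c < sz) for c, sz in zip(loc, s.labels_loc.shape)):
        return
    # mirror the owner's change in our ghost copy
    s.labels_loc[loc] = hp.new
    own = s.labels_loc[s.owned]
    # owned face neighbours of the hot ghost matching the old label
    seeds = []
    for ax in range(own.ndim):
        for d in (-1, 1):
            c = list(loc)
            c[ax] += d
            oc = tuple(v - s.owned[a].start for a, v in enumerate(c))
            if all(0 <= v < own.shape[a] for a, v in enumerate(oc)):
                if int(own[oc]) == hp.old:
                    seeds.append(oc)
    if not seeds or hp.old == hp.new:
        return
    comp, _ = ndimage.label(own == hp.old, structure=st)
    ids = {int(comp[c]) for c in seeds if comp[c] > 0}
    for i in ids:
        own[comp == i] = hp.new


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

@dataclass
class DistResult:
    labels: np.ndarray
    trace: EnergyTrace
    converged: bool
    iterations: int
    stats: RunStats


def _stats_copies(rt: SimRuntime) -> None:
    rt._stats_cache = {}


def _rt_stats_copy(rt: SimRuntime, rank: int) -> RegionStats:
    cache = getattr(rt, "_stats_cache", None)
    if cache is None:
        rt._stats_cache = cache = {}
    if rank not in cache:
        cache[rank] = rt.stats_global.copy()
    return cache[rank]


SimRuntime.stats_global_copy = _rt_stats_copy


def run_distributed(image, init_labels, p: EnergyParams, dims: Sequence[int],
                    rt_config: Optional[dict] = None, max_iter: int = 1000,
                    conn: Optional[Connectivity] = None) -> DistResult:
    """Full distributed run: scatter, global label initialization, then
    checkerboard contour propagation with hot-particle re-labeling until no
    rank accepts a move.

    With a 1x1 domain grid the result (labels and energy trace) is
    bit-identical to ``run_sequential``.
    """
    cfg = rt_config or {}
    rt = SimRuntime(image, init_labels, p, dims,
                    g=cfg.get("g"), conn=conn, order=cfg.get("order"))
    initial_global_labels(rt)
    exchange_ghosts(rt.states, rt.grid, "labels")
    exchange_ghosts(rt.states, rt.grid, "image")

    rt.stats_global = rt.allreduce_stats()
    rt.alloc_base = int(max((int(s.labels_loc[s.owned].max(initial=0))
                             for s in rt.states), default=0))
    if p.model == "ps":
        for r in rt.order:
            s = rt.states[r]
            rt.scratch.setdefault(r, {})["maps_post"] = \
                PSMaps(s.image_loc, s.labels_loc, p.radius)
    rt.trace.append(rt.global_energy(rt.stats_global))

    converged = False
    it = 0
    while it < max_iter:
        rt.scratch["_messages"] = 0
        _stats_copies(rt)
        for r in range(rt.grid.n_ranks):
            if r in rt.scratch and isinstance(rt.scratch.get(r), dict):
                rt.scratch[r].pop("maps_post", None)
        executed = contour_propagation_step(rt)
        n_acc = rt.scratch["_accepted"]
        if n_acc == 0:
            converged = True
            break
        relabel_regions(rt)
        it += 1
        exchange_ghosts(rt.states, rt.grid, "labels")
        rt.stats_global = rt.allreduce_stats()
        rt.alloc_base = max(rt.alloc_base,
                            max(rt.scratch[r]["alloc_high"]
                                for r in range(rt.grid.n_ranks)))
        if p.model == "ps":
            for r in rt.order:
                s = rt.states[r]
                rt.scratch[r]["maps_post"] = PSMaps(s.image_loc, s.labels_loc,
                                                    p.radius)
        e = rt.global_energy(rt.stats_global)
        rt.trace.append(e)
        rt.runstats.energy.append(e)
        rt.runstats.accepted.append(n_acc)
        rt.runstats.messages.append(rt.scratch["_messages"])
        rt.runstats.hot_particles.append(rt.scratch.get("_hot", 0))
        rt.runstats.relabel_rounds.append(rt.scratch.get("_rounds", 0))
        # local oscillation control
        for r in rt.order:
            s = rt.states[r]
            acc = [( int(_local_to_global_flat(np.array([v]), s, rt.grid.shape)[0]),
                     a, b) for v, a, b in rt.scratch[r]["exec"].accepted]
            detect_oscillation(rt.osc[r], acc, rt.trace.energies)

    labels = rt.gather_labels()
    return DistResult(labels, rt.trace, converged, it, rt.runstats)
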