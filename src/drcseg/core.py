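"""Grid data model for discrete region-competition segmentation.

A segmentation state is a pair of equally shaped arrays: a real-valued
intensity field and an integer label field partitioning the pixel grid into
one background region (label 0) and any number of foreground regions
(positive labels).  Foreground regions are face-connected (4-connected in
2D, 6-connected in 3D); the background uses the complementary full
connectivity (8 / 26).  The image border behaves like an infinite background
for all connectivity and contour tests.

Coordinates are 0-based, (z,)y,x order, row-major.  Labels are arbitrary
positive integers and are never recycled within a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage

Pixel = Tuple[int, ...]

LABEL_DTYPE = np.int32


# ---------------------------------------------------------------------------
# connectivity conventions
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _offsets(ndim: int, full: bool) -> Tuple[Pixel, ...]:
    offs = []
    for idx in np.ndindex(*(3,) * ndim):
        off = tuple(int(i) - 1 for i in idx)
        if all(o == 0 for o in off):
            continue
        if full or sum(abs(o) for o in off) == 1:
            offs.append(off)
    return tuple(sorted(offs))


@dataclass(frozen=True)
class Connectivity:
    """Face adjacency for foreground, full adjacency for background."""

    ndim: int
    fg_neighbors: Tuple[Pixel, ...]
    bg_neighbors: Tuple[Pixel, ...]

    @classmethod
    def from_ndim(cls, ndim: int) -> "Connectivity":
        if ndim not in (2, 3):
            raise ValueError(f"dimensionality must be 2 or 3, got {ndim}")
        return cls(ndim, _offsets(ndim, full=False), _offsets(ndim, full=True))


def face_structure(ndim: int) -> np.ndarray:
    """scipy structuring element for face connectivity."""
    return ndimage.generate_binary_structure(ndim, 1)


def full_structure(ndim: int) -> np.ndarray:
    """scipy structuring element for full (vertex) connectivity."""
    return ndimage.generate_binary_structure(ndim, ndim)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageVolume:
    """A d-dimensional (d in {2, 3}) grayscale intensity field.

    Intensities are stored as float64.  Negative input raises: region
    competition energies assume non-negative photon-count-like data.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise ValueError("image must be 2D or 3D")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all image extents must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("image intensities must be non-negative")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim


@dataclass
class LabelField:
    """Per-pixel region labels: 0 is background, positive values are FG."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=LABEL_DTYPE)
        if self.labels.ndim not in (2, 3):
            raise ValueError("label field must be 2D or 3D")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.labels.shape

    def validate_connectivity(self) -> None:
        """Assert every live FG label is one face-connected component."""
        st = face_structure(self.labels.ndim)
        for lab in np.unique(self.labels):
            if lab == 0:
                continue
            _, n = ndimage.label(self.labels == lab, structure=st)
            if n != 1:
                raise ValueError(f"label {lab} has {n} face-connected components")


def as_image(image) -> np.ndarray:
    if isinstance(image, ImageVolume):
        return image.data
    return ImageVolume(np.asarray(image)).data


def as_labels(labels) -> np.ndarray:
    if isinstance(labels, LabelField):
        return labels.labels
    return LabelField(np.asarray(labels)).labels


@dataclass(frozen=True)
class Particle:
    """A contour pixel of a foreground region.

    ``active`` marks "hot" particles during distributed re-labeling.
    """

    pixel: Pixel
    label: int
    active: bool = False


# ---------------------------------------------------------------------------
# contour extraction
# ---------------------------------------------------------------------------

def neighbor_label_stack(labels: np.ndarray, offsets: Sequence[Pixel],
                         fill: int = 0) -> np.ndarray:
    """Stack of neighbour labels, shape (len(offsets),) + labels.shape.

    Out-of-grid neighbours are reported as ``fill`` (default 0: the image
    border is permanent background).
    """
    out = np.empty((len(offsets),) + labels.shape, dtype=labels.dtype)
    for k, off in enumerate(offsets):
        plane = out[k]
        plane.fill(fill)
        src = tuple(slice(max(o, 0), labels.shape[a] + min(o, 0))
                    for a, o in enumerate(off))
        dst = tuple(slice(max(-o, 0), labels.shape[a] + min(-o, 0))
                    for a, o in enumerate(off))
        plane[dst] = labels[src]
    return out


def contour_mask(labels: np.ndarray, conn: Connectivity | None = None) -> np.ndarray:
    """Boolean mask of FG pixels with a face neighbour of a different label."""
    labels = np.asarray(labels)
    conn = conn or Connectivity.from_ndim(labels.ndim)
    nb = neighbor_label_stack(labels, conn.fg_neighbors, fill=0)
    differs = np.any(nb != labels[None, ...], axis=0)
    return (labels > 0) & differs


def extract_contour_particles(labels, conn: Connectivity | None = None) -> Set[Particle]:
    """All FG pixels having at least one face neighbour with a different label.

    Pixels outside the grid count as background, so FG pixels on the image
    border are always contour particles.
    """
    arr = as_labels(labels)
    conn = conn or Connectivity.from_ndim(arr.ndim)
    mask = contour_mask(arr, conn)
    coords = np.argwhere(mask)
    return {Particle(tuple(int(c) for c in pt), int(arr[tuple(pt)]))
            for pt in coords}


# ---------------------------------------------------------------------------
# region sufficient statistics
# ---------------------------------------------------------------------------

class RegionStats:
    """Per-label pixel count, intensity sum and sum of squares.

    Backed by dense arrays indexed by label so that vectorized energy
    difference evaluation can gather statistics for thousands of candidate
    moves at once.  Incremental single-pixel updates are exact (plain sums).
    """

    __slots__ = ("n", "s", "q")

    def __init__(self, max_label: int = 0):
        size = max(int(max_label) + 1, 1)
        self.n = np.zeros(size, dtype=np.int64)
        self.s = np.zeros(size, dtype=np.float64)
        self.q = np.zeros(size, dtype=np.float64)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_fields(cls, image, labels) -> "RegionStats":
        img = as_image(image)
        lab = as_labels(labels)
        if img.shape != lab.shape:
            raise ValueError("image and label field shapes differ")
        flat = lab.ravel()
        vals = img.ravel()
        m = int(flat.max(initial=0))
        st = cls(m)
        st.n = np.bincount(flat, minlength=m + 1).astype(np.int64)
        st.s = np.bincount(flat, weights=vals, minlength=m + 1)
        st.q = np.bincount(flat, weights=vals * vals, minlength=m + 1)
        return st

    def copy(self) -> "RegionStats":
        out = RegionStats(len(self.n) - 1)
        out.n = self.n.copy()
        out.s = self.s.copy()
        out.q = self.q.copy()
        return out

    # -- bookkeeping ---------------------------------------------------------

    def _grow(self, label: int) -> None:
        if label >= len(self.n):
            extra = label + 1 - len(self.n)
            self.n = np.concatenate([self.n, np.zeros(extra, dtype=np.int64)])
            self.s = np.concatenate([self.s, np.zeros(extra)])
            self.q = np.concatenate([self.q, np.zeros(extra)])

    def live_labels(self) -> np.ndarray:
        labs = np.nonzero(self.n)[0]
        return labs

    def mean(self, label: int) -> float:
        if self.n[label] == 0:
            raise KeyError(f"label {label} has no pixels")
        return float(self.s[label] / self.n[label])

    def move_pixel(self, value: float, l_from: int, l_to: int) -> None:
        """Relabel one pixel of intensity ``value`` from l_from to l_to."""
        self._grow(max(l_from, l_to))
        self.n[l_from] -= 1
        self.s[l_from] -= value
        self.q[l_from] -= value * value
        self.n[l_to] += 1
        self.s[l_to] += value
        self.q[l_to] += value * value
        if self.n[l_from] == 0 and l_from != 0:
            self.s[l_from] = 0.0
            self.q[l_from] = 0.0

    def merge(self, l_keep: int, l_gone: int) -> None:
        """Fuse region ``l_gone`` into ``l_keep``."""
        self._grow(max(l_keep, l_gone))
        self.n[l_keep] += self.n[l_gone]
        self.s[l_keep] += self.s[l_gone]
        self.q[l_keep] += self.q[l_gone]
        self.n[l_gone] = 0
        self.s[l_gone] = 0.0
        self.q[l_gone] = 0.0

    def transfer(self, pixels_values: np.ndarray, l_from: int, l_to: int) -> None:
        """Move a whole pixel set (given by its intensity values) between labels."""
        self._grow(max(l_from, l_to))
        cnt = len(pixels_values)
        tot = float(np.sum(pixels_values))
        tot2 = float(np.sum(pixels_values * pixels_values))
        self.n[l_from] -= cnt
        self.s[l_from] -= tot
        self.q[l_from] -= tot2
        self.n[l_to] += cnt
        self.s[l_to] += tot
        self.q[l_to] += tot2
        if self.n[l_from] == 0 and l_from != 0:
            self.s[l_from] = 0.0
            self.q[l_from] = 0.0

    # -- comparison ----------------------------------------------------------

    def as_dict(self) -> Dict[int, Tuple[int, float, float]]:
        out = {}
        for lab in range(len(self.n)):
            if self.n[lab] > 0 or lab == 0:
                out[lab] = (int(self.n[lab]), float(self.s[lab]), float(self.q[lab]))
        return out

    def allclose(self, other: "RegionStats", rtol: float = 1e-9) -> bool:
        a, b = self.as_dict(), other.as_dict()
        if set(a) != set(b):
            return False
        for lab in a:
            na, sa, qa = a[lab]
            nb, sb, qb = b[lab]
            if na != nb:
                return False
            if not np.isclose(sa, sb, rtol=rtol, atol=1e-12):
                return False
            if not np.isclose(qa, qb, rtol=rtol, atol=1e-12):
                return False
        return True


def region_statistics(image, labels) -> RegionStats:
    """Exact per-label sufficient statistics (count, sum, sum of squares)."""
    return RegionStats.from_fields(image, labels)


# ---------------------------------------------------------------------------
# misc helpers shared by the drivers
# ---------------------------------------------------------------------------

def normalize_labels(labels) -> np.ndarray:
    """Relabel the FG mask as its face-connected components, 1..K.

    Components are numbered in raster order of their first pixel, which makes
    the numbering deterministic and identical to the distributed min-label
    relaxation result for a single rank.
    """
    lab = as_labels(labels)
    st = face_structure(lab.ndim)
    out, _ = ndimage.label(lab > 0, structure=st)
    return out.astype(LABEL_DTYPE)


def perimeter_pairs(labels: np.ndarray) -> int:
    """Number of in-grid face-adjacent pixel pairs with differing labels."""
    total = 0
    for ax in range(labels.ndim):
        a = np.moveaxis(labels, ax, 0)
        total += int(np.count_nonzero(a[:-1] != a[1:]))
    return total
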