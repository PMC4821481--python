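"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from drcseg.core import LABEL_DTYPE, face_structure


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_label_field(rng: np.random.Generator, shape, fg_fraction=0.4,
                       smooth=1.0) -> np.ndarray:
    """A realistic random partition: thresholded smoothed noise, labeled by
    face-connected components (so every FG label is one component)."""
    noise = rng.normal(size=shape)
    if smooth > 0:
        noise = ndimage.gaussian_filter(noise, smooth)
    thr = np.quantile(noise, 1.0 - fg_fraction)
    mask = noise > thr
    labels, _ = ndimage.label(mask, structure=face_structure(len(shape)))
    return labels.astype(LABEL_DTYPE)


def flood_fill_components(mask: np.ndarray) -> np.ndarray:
    """Independent connected-component oracle: BFS flood fill, face
    connectivity, raster seed order (no scipy)."""
    out = np.zeros(mask.shape, dtype=np.int64)
    nxt = 0
    offsets = []
    for ax in range(mask.ndim):
        for d in (-1, 1):
            off = [0] * mask.ndim
            off[ax] = d
            offsets.append(tuple(off))
    for start in np.argwhere(mask):
        start = tuple(int(c) for c in start)
        if out[start]:
            continue
        nxt += 1
        stack = [start]
        out[start] = nxt
        while stack:
            cur = stack.pop()
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= v < s for v, s in zip(nb, mask.shape)):
                    if mask[nb] and not out[nb]:
                        out[nb] = nxt
                        stack.append(nb)
    return out


def labelings_equal_up_to_bijection(a: np.ndarray, b: np.ndarray) -> bool:
    """Same partition: a bijection between FG label sets maps a onto b."""
    if a.shape != b.shape:
        return False
    if np.any((a > 0) != (b > 0)):
        return False
    fa, fb = a[a > 0], b[a > 0]
    pairs = set(zip(fa.tolist(), fb.tolist()))
    return (len({p[0] for p in pairs}) == len(pairs)
            and len({p[1] for p in pairs}) == len(pairs))


def component_counts(labels: np.ndarray) -> dict:
    """Face-connected component count per FG label (scipy oracle)."""
    st = face_structure(labels.ndim)
    out = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        _, n = ndimage.label(labels == lab, structure=st)
        out[int(lab)] = n
    return out
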