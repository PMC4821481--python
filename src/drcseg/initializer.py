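"""Initial segmentations: bubble grids, blurred local maxima, thresholding,
and bounding box."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import filters

from .core import LABEL_DTYPE, as_image, face_structure, full_structure
from .energy import ball_offsets

DEFAULT_SEED_RADIUS = 3


def _paint_ball(mask: np.ndarray, center: Sequence[int], radius: int) -> None:
    for off in ball_offsets(int(radius), mask.ndim):
        y = tuple(int(c) + o for c, o in zip(center, off))
        if all(0 <= v < s for v, s in zip(y, mask.shape)):
            mask[y] = True


def init_bubbles(shape: Sequence[int], counts_per_axis: Sequence[int],
                 radius: int) -> np.ndarray:
    """Axis-uniform grid of disk/ball seeds, one label per bubble.

    Centers sit at the cell centers of the counts grid; bubbles must fit
    without overlapping.
    """
    shape = tuple(int(s) for s in shape)
    counts = tuple(int(c) for c in counts_per_axis)
    if len(counts) != len(shape):
        raise ValueError("counts dimensionality does not match shape")
    for s, c in zip(shape, counts):
        if c < 1:
            raise ValueError("counts must be >= 1")
        if s / c < 2 * radius + 1:
            raise ValueError("bubble radius too large for the grid spacing")
    labels = np.zeros(shape, dtype=LABEL_DTYPE)
    lab = 0
    for idx in np.ndindex(*counts):
        lab += 1
        center = tuple(int((i + 0.5) * s / c) for i, s, c in zip(idx, shape, counts))
        mask = np.zeros(shape, dtype=bool)
        _paint_ball(mask, center, radius)
        if np.any(labels[mask] != 0):
            raise ValueError("bubbles overlap")
        labels[mask] = lab
    return labels


def init_local_maxima(image, sigma: float, radius: int = DEFAULT_SEED_RADIUS
                      ) -> np.ndarray:
    """Disk/ball seeds around local maxima of the Gaussian-blurred image.

    A maximum is a full-connectivity plateau strictly above all its outside
    neighbours; a plateau contributes one seed at its lexicographically
    smallest pixel.  Overlapping or touching seeds merge into one label.
    No maxima yields a valid all-background field.
    """
    img = as_image(image)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    blurred = ndimage.gaussian_filter(img, sigma) if sigma > 0 else img
    full = full_structure(img.ndim)
    foot = np.ones((3,) * img.ndim, dtype=bool)
    nbr_max = ndimage.maximum_filter(blurred, footprint=foot, mode="constant",
                                     cval=-np.inf)
    cand = blurred >= nbr_max  # plateau pixels at least as high as everything around
    comp, n = ndimage.label(cand, structure=full)
    mask = np.zeros(img.shape, dtype=bool)
    for i in range(1, n + 1):
        sel = comp == i
        # a maximum plateau needs a strictly lower outside ring; a plateau
        # covering the whole image (constant data) is not a maximum
        ring = ndimage.binary_dilation(sel, structure=full) & ~sel
        if not np.any(ring):
            continue
        if blurred[ring].max() >= blurred[sel].max():
            continue
        seed = tuple(int(c) for c in np.argwhere(sel)[0])
        _paint_ball(mask, seed, radius)
    out, _ = ndimage.label(mask, structure=face_structure(img.ndim))
    return out.astype(LABEL_DTYPE)


def init_threshold(image, mode: str = "otsu",
                   value: Optional[float] = None) -> np.ndarray:
    """Threshold the image and label the face-connected mask components."""
    img = as_image(image)
    if mode == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        t = float(value)
    elif mode == "otsu":
        t = float(filters.threshold_otsu(img))
    elif mode == "li":
        t = float(filters.threshold_li(img))
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    mask = img > t
    out, _ = ndimage.label(mask, structure=face_structure(img.ndim))
    return out.astype(LABEL_DTYPE)


def init_bounding_box(shape: Sequence[int], margin: int) -> np.ndarray:
    """One FG region filling the image eroded by ``margin`` on every side."""
    shape = tuple(int(s) for s in shape)
    if margin < 1:
        raise ValueError("margin must be >= 1")
    if any(2 * margin >= s for s in shape):
        raise ValueError("margin too large for the image extents")
    labels = np.zeros(shape, dtype=LABEL_DTYPE)
    inner = tuple(slice(margin, s - margin) for s in shape)
    labels[inner] = 1
    return labels
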