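"""Synthetic benchmark images: periodic tilings of ellipsoid unit cells.

The generator emulates scalable segmentation workloads: a unit cell holds
non-overlapping ellipsoids of distinct intensities on a uniform background,
in a variant where every object stays clear of the cell boundary and one
where a fraction of objects wraps across the periodic boundary.  Tiling
unit cells produces arbitrarily large images whose wrapped objects become
contiguous across internal seams.  Exact ground-truth labels accompany
every image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import LABEL_DTYPE, face_structure

DEFAULT_BG = 10.0
# the intensity floor keeps every object in the growth regime of the
# contour-length prior: flat-front growth needs (c - bg)^2 > 2*lambda on
# the normalized scale, i.e. contrast > 0.28*255 for lambda = 0.04
DEFAULT_INTENSITY_RANGE = (100.0, 250.0)
_N_INTENSITY_LEVELS = 40
_PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class EllipsoidSpec:
    """One generated object: center, semi-axes (pixels), intensity, label."""

    center: Tuple[float, ...]
    semi_axes: Tuple[float, ...]
    intensity: float
    label: int


def _ellipsoid_mask(shape: Sequence[int], center: Sequence[float],
                    semi_axes: Sequence[float], periodic: bool) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a, s in zip(grids, center, semi_axes, shape):
        d = g - c
        if periodic:
            d = d - np.round(d / s) * s  # minimal periodic displacement
        acc += (d / a) ** 2
    return acc <= 1.0


def make_unit_cell(shape: Sequence[int], n_objects: int,
                   crossing: bool = False,
                   intensity_range: Tuple[float, float] = DEFAULT_INTENSITY_RANGE,
                   bg_level: float = DEFAULT_BG,
                   seed: int = 0,
                   crossing_fraction: float = 0.25,
                   semi_axis_range: Tuple[float, float] | None = None,
                   min_gap: int = 1
                   ) -> Tuple[np.ndarray, np.ndarray, List[EllipsoidSpec]]:
    """A unit cell of non-overlapping ellipsoids with ground-truth labels.

    ``crossing=False`` keeps every ellipsoid at least 2 pixels away from
    the cell boundary; ``crossing=True`` places a quarter of the objects
    (by default) across the periodic boundary, wrapped.  Intensities are
    distinct, sampled without replacement from evenly spaced levels over
    ``intensity_range``.  Placement is by rejection sampling; a clearance
    of ``min_gap`` pixels between objects keeps ground-truth components
    distinct (larger gaps guarantee one blurred-intensity maximum per
    object for seed-based initialization).
    """
    shape = tuple(int(s) for s in shape)
    ndim = len(shape)
    if ndim not in (2, 3):
        raise ValueError("shape must be 2D or 3D")
    rng = np.random.default_rng(seed)
    if semi_axis_range is None:
        semi_axis_range = (4.0, 10.0) if ndim == 2 else (3.0, 8.0)
    levels = np.linspace(intensity_range[0], intensity_range[1],
                         _N_INTENSITY_LEVELS)
    intensities = rng.choice(levels, size=n_objects, replace=False)

    occupied = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=LABEL_DTYPE)
    image = np.full(shape, float(bg_level), dtype=np.float64)
    specs: List[EllipsoidSpec] = []
    n_cross = int(round(crossing_fraction * n_objects)) if crossing else 0
    st = face_structure(ndim)

    for i in range(n_objects):
        wraps = i < n_cross
        placed = False
        for _ in range(_PLACEMENT_ATTEMPTS):
            axes = tuple(float(rng.uniform(*semi_axis_range)) for _ in range(ndim))
            if wraps:
                # center near a boundary so the object wraps around
                ax_cross = int(rng.integers(ndim))
                center = []
                for a in range(ndim):
                    if a == ax_cross:
                        edge = float(rng.uniform(-axes[a] / 2, axes[a] / 2))
                        center.append(edge % shape[a])
                    else:
                        center.append(float(rng.uniform(0, shape[a])))
                center = tuple(center)
            else:
                center = tuple(float(rng.uniform(axes[a] + 2.0,
                                                 shape[a] - axes[a] - 2.0))
                               for a in range(ndim))
            mask = _ellipsoid_mask(shape, center, axes, periodic=wraps)
            if mask.sum() < 3:
                continue
            grown = ndimage.binary_dilation(mask, structure=st,
                                            iterations=max(int(min_gap), 1))
            if np.any(grown & occupied):
                continue
            if wraps:
                # must genuinely touch both opposite faces along some axis
                touches = False
                for a in range(ndim):
                    first = np.moveaxis(mask, a, 0)[0]
                    last = np.moveaxis(mask, a, 0)[-1]
                    if np.any(first) and np.any(last):
                        touches = True
                if not touches:
                    continue
            occupied |= grown
            lab = i + 1
            labels[mask] = lab
            image[mask] = float(intensities[i])
            specs.append(EllipsoidSpec(center, axes, float(intensities[i]), lab))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place object {i + 1}/{n_objects} within "
                f"{_PLACEMENT_ATTEMPTS} attempts")
    return image, labels, specs


def tile_periodic(cell_image: np.ndarray, cell_labels: np.ndarray,
                  reps_per_axis: Sequence[int]) -> Tuple[np.ndarray, np.ndarray]:
    """Periodically concatenate the unit cell; labels are re-uniquified as
    face-connected components so wrapped objects become single regions
    across internal seams."""
    reps = tuple(int(r) for r in reps_per_axis)
    if any(r < 1 for r in reps):
        raise ValueError("reps must be >= 1")
    image = np.tile(cell_image, reps)
    mask = np.tile(cell_labels > 0, reps)
    labels, _ = ndimage.label(mask, structure=face_structure(mask.ndim))
    return image, labels.astype(LABEL_DTYPE)


def add_noise(image: np.ndarray, model: str = "gaussian", level: float = 5.0,
              seed: int = 0) -> np.ndarray:
    """Reproducible noise: additive Gaussian (clipped at 0) or
    mean-preserving Poisson with gain ``level``."""
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if level == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    if model == "gaussian":
        out = image + rng.normal(0.0, level, size=image.shape)
        return np.clip(out, 0.0, None)
    if model == "poisson":
        return rng.poisson(image / level).astype(np.float64) * level
    raise ValueError(f"unknown noise model {model!r}")


def specs_to_rows(specs: Sequence[EllipsoidSpec]) -> List[dict]:
    """Manifest rows (one dict per object) for CSV export."""
    rows = []
    for sp in specs:
        row = {"label": sp.label, "intensity": sp.intensity}
        for a, (c, ax) in enumerate(zip(sp.center, sp.semi_axes)):
            row[f"center_{a}"] = c
            row[f"semi_axis_{a}"] = ax
        rows.append(row)
    return rows
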