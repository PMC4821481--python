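"""Reproducible benchmark conditions for sequential/distributed agreement.

The agreement suite measures how closely the distributed runs track the
sequential algorithm on seeded synthetic images segmented with identical
parameters:

* 10 piecewise-constant 2D fixtures (128^2, 8-12 ellipsoids, Gaussian noise
  sigma = 5 on the 8-bit scale, normalized to [0, 1]), initialized from
  local maxima (sigma = 5) of the clean intensity field;
* 5 piecewise-smooth fixtures on the same images, initialized by Li
  thresholding of the noisy image;
* domain grids (2, 2) and (2, 4).

Reported quantities: the relative difference of the converged energy, the
maximum relative energy difference anywhere along the iteration-aligned
traces (shorter trace padded with its final value), and the number of
differing pixels after overlap-maximal label matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import contour_mask
from .energy import EnergyParams
from .initializer import init_local_maxima, init_threshold
from .io_cli import compare_labelings
from .optimizer import run_sequential
from .distributed import run_distributed
from .synthetic import add_noise, make_unit_cell

INTENSITY_SCALE = 255.0
NOISE_SIGMA = 5.0

PC_PARAMS = EnergyParams(model="pc", noise="gaussian", lam=0.04, theta=0.02,
                         r_kappa=4)
PS_PARAMS = EnergyParams(model="ps", noise="gaussian", lam=0.04, theta=0.02,
                         r_kappa=4, beta=0.05, radius=8)

DIMS_2D = ((2, 2), (2, 4))


def pc_fixture(seed: int, shape=(128, 128), n_objects: Optional[int] = None):
    """Noisy PC benchmark image with clean-field local-maxima seeds."""
    if n_objects is None:
        n_objects = 8 + (seed % 5)
    clean, truth, _ = make_unit_cell(shape, n_objects, seed=seed)
    img = add_noise(clean, "gaussian", NOISE_SIGMA, seed=seed + 100)
    img = img / INTENSITY_SCALE
    init = init_local_maxima(clean / INTENSITY_SCALE, 5.0, 3)
    return img, init, truth


def ps_fixture(seed: int, shape=(128, 128), n_objects: Optional[int] = None):
    """Noisy PS benchmark image with Li-threshold initialization."""
    if n_objects is None:
        n_objects = 8 + (seed % 5)
    clean, truth, _ = make_unit_cell(shape, n_objects, seed=seed)
    img = add_noise(clean, "gaussian", NOISE_SIGMA, seed=seed + 100)
    img = img / INTENSITY_SCALE
    init = init_threshold(img, "li")
    return img, init, truth


@dataclass
class AgreementCase:
    """Sequential-vs-distributed comparison for one fixture and grid."""

    model: str
    seed: int
    dims: Tuple[int, ...]
    energy_seq: float
    energy_dist: float
    trace_seq: List[float]
    trace_dist: List[float]
    n_diff_pixels: int
    diff_on_boundary: bool
    converged: bool
    labels_seq: Optional[np.ndarray] = None
    labels_dist: Optional[np.ndarray] = None

    @property
    def final_energy_rel_pct(self) -> float:
        return 100.0 * abs(self.energy_dist - self.energy_seq) / abs(self.energy_seq)

    @property
    def trace_rel_pct(self) -> float:
        a = np.asarray(self.trace_seq, dtype=float)
        b = np.asarray(self.trace_dist, dtype=float)
        n = max(len(a), len(b))
        a = np.concatenate([a, np.full(n - len(a), a[-1])])
        b = np.concatenate([b, np.full(n - len(b), b[-1])])
        return float(np.max(100.0 * np.abs(b - a) / np.abs(a)))


def _diff_pixels_on_boundary(labels_a: np.ndarray, labels_b: np.ndarray,
                             matched: Sequence[Tuple[int, int]]) -> bool:
    """All differing pixels sit on a region boundary of one of the results."""
    mapping = np.zeros(int(labels_b.max()) + 1, dtype=np.int64)
    mapping[:] = -np.arange(len(mapping)) - 1
    mapping[0] = 0
    for pa, pb in matched:
        mapping[pb] = pa
    bm = mapping[labels_b]
    diff = bm != labels_a
    if not np.any(diff):
        return True
    on_a = contour_mask(labels_a) | _bg_boundary(labels_a)
    on_b = contour_mask(labels_b) | _bg_boundary(labels_b)
    return bool(np.all((on_a | on_b)[diff]))


def _bg_boundary(labels: np.ndarray) -> np.ndarray:
    """BG pixels face-adjacent to any FG region."""
    from scipy import ndimage
    from .core import face_structure
    fg = labels > 0
    grown = ndimage.binary_dilation(fg, structure=face_structure(labels.ndim))
    return grown & ~fg


def run_agreement_case(model: str, seed: int, dims, max_iter: int = 500
                       ) -> AgreementCase:
    if model == "pc":
        img, init, _ = pc_fixture(seed)
        p = PC_PARAMS
    else:
        img, init, _ = ps_fixture(seed)
        p = PS_PARAMS
    seq = run_sequential(img, init, p, max_iter=max_iter)
    dist = run_distributed(img, init, p, dims, max_iter=max_iter)
    cmpres = compare_labelings(seq.labels, dist.labels)
    on_b = _diff_pixels_on_boundary(seq.labels, dist.labels, cmpres.matched_pairs)
    return AgreementCase(model, seed, tuple(dims),
                         seq.trace.energies[-1], dist.trace.energies[-1],
                         seq.trace.energies, dist.trace.energies,
                         cmpres.n_diff_pixels, on_b,
                         seq.converged and dist.converged,
                         labels_seq=seq.labels, labels_dist=dist.labels)


def agreement_suite(base_seed: int = 1, max_iter: int = 500,
                    dims_list=DIMS_2D) -> List[AgreementCase]:
    """The full 15-fixture suite: seeds base..base+9 PC, base+10..base+14 PS."""
    cases = []
    for i in range(10):
        for dims in dims_list:
            cases.append(run_agreement_case("pc", base_seed + i, dims, max_iter))
    for i in range(10, 15):
        for dims in dims_list:
            cases.append(run_agreement_case("ps", base_seed + i, dims, max_iter))
    return cases


def summarize(cases: Sequence[AgreementCase]) -> Dict[str, float]:
    return {
        "t1": max(c.final_energy_rel_pct for c in cases),
        "t2": max(c.trace_rel_pct for c in cases),
        "t3": max(c.n_diff_pixels for c in cases),
    }
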