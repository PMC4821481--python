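# drcseg

Discrete region competition segmentation for 2D/3D grayscale images, with a
distributed-memory layer running on a deterministic simulated
message-passing runtime.

Modern light-sheet and confocal microscopes produce 3D images too large to
segment on a single machine at acquisition rate. One answer is to decompose
the image into blocks, distribute them across ranks, and let the ranks
collectively minimize a single global segmentation energy. `drcseg`
implements both the sequential algorithm and the distributed machinery —
checkerboard resolution of cross-boundary move conflicts, parallel
connected-component label initialization, and hot-particle region
re-labeling — so the agreement between the two can be studied exactly, at
desk scale, without a cluster.

## The model

A label field partitions the pixel grid Ω ⊂ Zᵈ (d = 2, 3) into a
background region X₀ and face-connected foreground regions X₁ … X_{M−1}.
Segmentation minimizes

    E = E_data + λ E_length + α E_merge

* `E_data` — a piecewise-constant (PC) fit, Σₗ Σ_{x∈Xₗ} (I(x) − μₗ)² under
  Gaussian noise or the Poisson negative log-likelihood Σₗ Σ (μₗ − I ln μₗ);
  or a piecewise-smooth (PS) fit that replaces μₗ by a local ball-window
  mean μₗ(x) of radius R, plus β times a roughness penalty
  Σ (μₗ(x) − μₗ(y))² over face-adjacent pairs inside each region.
* `E_length` — the number of face-adjacent pixel pairs with differing
  labels (the discrete contour length), weighted by λ.
* `E_merge` — region fusion control: two regions may fuse only when their
  mean intensities differ by at most θ; fusing moves can carry an additive
  penalty α (0 by default).

Contours are deformed by *particles*: each candidate move relabels one
boundary pixel and is priced by the exact energy difference ΔE. Moves
sharing pixels form a causal-dependency graph; in every maximal connected
sub-graph only the best move executes per iteration. Digital topology keeps
foreground regions face-connected: moves are classified simple, splitting,
fusing, or forbidden, and splits/fusions relabel regions deterministically.

In distributed mode each rank owns one block plus ghost layers. Blocks are
checkerboard-colored; black ranks resolve their boundary sub-graphs first
and ship the decisions to white neighbours, which accept them verbatim and
fill in only compatible moves. Label changes crossing block boundaries
propagate by "hot" particles that seed flood fills on the receiving rank,
iterating to a global fixed point. The runtime is simulated with per-round
message queues, so every run is bit-reproducible and independent of rank
scheduling — a 1×1 grid is bit-identical to the sequential driver.

## Worked example

```python
import numpy as np
from drcseg import (EnergyParams, init_local_maxima, run_sequential,
                    run_distributed, compare_labelings)
from drcseg.synthetic import make_unit_cell, add_noise

clean, truth, specs = make_unit_cell((128, 128), 9, seed=1)
image = add_noise(clean, "gaussian", 5.0, seed=101) / 255.0
init = init_local_maxima(clean / 255.0, sigma=5.0, radius=3)
params = EnergyParams(model="pc", noise="gaussian", lam=0.04, theta=0.02,
                      r_kappa=4)

seq = run_sequential(image, init, params)
dist = run_distributed(image, init, params, dims=(2, 2))
cmp = compare_labelings(seq.labels, dist.labels)
print(f"sequential:  {seq.iterations} iterations, final energy {seq.trace.energies[-1]:.3f}")
print(f"distributed: {dist.iterations} iterations, final energy {dist.trace.energies[-1]:.3f}")
print(f"regions found: {len(np.unique(seq.labels)) - 1} (ground truth {len(specs)})")
print(f"differing pixels after label matching: {cmp.n_diff_pixels}")
```

prints

```
sequential:  12 iterations, final energy 26.446
distributed: 12 iterations, final energy 26.446
regions found: 9 (ground truth 9)
differing pixels after label matching: 0
```

Nine noisy ellipsoids are discovered from nine automatically detected
seeds; the four-subdomain distributed run converges to the same energy and,
after matching the (arbitrary) label names, to the pixel-identical
segmentation.

There is also a CLI:

```sh
drcseg synth --shape 128,128 --objects 9 --seed 1 --noise-model gaussian \
       --noise-level 5 --out-image img.tif --out-truth truth.tif
drcseg segment --input img.tif --output seg.tif --model pc \
       --lambda 10.4 --theta 5.1 --rkappa 4 --init maxima --sigma 5 \
       --domains 2,2 --trace trace.csv
drcseg compare --a truth.tif --b seg.tif --report report.csv
```

(CLI runs operate on raw intensities; scale λ and θ accordingly.)

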