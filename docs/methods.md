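# Methods

## Model and optimization

`drcseg` segments a d-dimensional grayscale image (d = 2, 3) by evolving a
label partition under the energy `E = E_data + λ·E_length + α·E_merge`.
Foreground (FG) regions are face-connected (4-/6-neighborhood); the
background (BG, label 0) uses the complementary full connectivity
(8-/26-neighborhood) and may change topology freely. The image border acts
as permanent background of infinite extent.

The optimizer is a greedy rank-based descent. Per iteration:

1. every contour pixel enumerates its candidate relabelings: a pixel may
   move to the label of any face neighbour (duplicates collapse to one
   move whose source is the lexicographically smallest neighbour carrying
   the target label);
2. each candidate is priced with the exact energy difference ΔE of the
   relabeling, computed from region sufficient statistics (PC) or local
   windows (PS) — `delta_energy` always equals the brute-force
   `total_energy` difference;
3. moves are classified topologically (simple / split / fuse / forbidden)
   and forbidden moves are pruned;
4. moves with ΔE < 0 form an undirected dependency graph (a move is an
   edge between its target and source pixel; edges sharing a pixel are
   causally dependent); in each maximal connected sub-graph only the move
   with the lowest ΔE survives (ties: lexicographic pixel, then target
   label);
5. surviving moves execute in deterministic (ΔE, pixel, target) order with
   per-move topological re-validation against the current state; moves
   invalidated by earlier moves of the same iteration are dropped;
6. fusions immediately relabel the higher label to the lower; potential
   splits (donor topological number > 1) are confirmed by flood fill at
   iteration end — the component containing the lexicographically smallest
   pixel keeps the old label, detached components receive fresh labels
   from a deterministic allocator. Labels are never recycled.

Convergence is reached when an iteration accepts no move. ΔE values are
computed once per iteration from the iteration-start state and reused
during execution; re-validation is topological only, which mirrors the
batch-acceptance structure of rank-based region competition. Region
statistics are refreshed from the fields at each iteration end, so
incremental rounding cannot drift.

### Energy terms

* PC-Gaussian: Σₗ Σ_{x∈Xₗ} (I(x) − μₗ)², evaluated from per-region
  (n, Σ I, Σ I²) as Σₗ (qₗ − sₗ²/nₗ).
* PC-Poisson: Σₗ (nₗ μₗ − sₗ ln μₗ) with μₗ clamped at 1e−8.
* PS: the regional mean is replaced by the ball-window estimate
  μₗ(x) = mean of I over {y : ‖y−x‖ ≤ R, label(y) = l}; β weighs the
  roughness penalty Σ (μₗ(x) − μₗ(y))² over face pairs within each region.
  Window count/sum maps are discrete convolutions with the Euclidean ball
  kernel (direct summation on small arrays, FFT on large ones). A single
  relabeling changes μ only within distance R, so its exact ΔE is computed
  on a window of half-width R+1 from the cached maps.
* E_length = number of in-grid face-adjacent pixel pairs with differing
  labels. Virtual pairs across the image border are not counted.
* E_merge is realized as admissibility: two FG regions may fuse only when
  their mean intensities differ by at most θ (inclusive); a fusing move
  additionally pays α (default 0, matching configurations in which θ alone
  governs fusion). A move that would make two regions face-adjacent
  through its target pixel is a fusing move; when the θ-test fails it is
  forbidden. Consequently dissimilar regions cannot exchange pixels
  directly — a modelling choice that keeps fusion control local and
  symmetric.
* Leave-one-out convention: the moved pixel is removed from its source
  region's statistics before both hypotheses are costed, avoiding
  self-bias for very small regions.

`delta_length` exposes a curvature proxy based on ball occupancy counts:
with B the discrete Euclidean ball of radius R_κ at the moved pixel,
`(|B ∩ X_from| − |B ∩ X_to| − 1)/|B|` is positive for moves sharpening the
contour (growing a protrusion) and ≈ 0 for moves along a straight edge (up
to the ±(2R_κ+1)/|B| discretization bias of the center column). It is a
standalone regularization primitive: the driver's move energies use the
exact perimeter-pair difference, so that accepted-move energies and the
total energy remain mutually consistent; R_κ otherwise determines the
ghost-layer width.

### Topological control

The donor region's topological number T — the number of face-connected
components of the donor label in the punctured full neighborhood that
touch the moved pixel — classifies removals: T = 1 is locally safe, T > 1
marks a potential split. T > 1 is necessary but not sufficient (removing
one pixel of a ring leaves it connected), so splits are confirmed by a
seeded flood fill. The classification is vectorized for whole move lists
via iterative minimum-propagation over the fixed neighborhood cell
adjacency.

### Oscillation damping

Greedy batch acceptance can oscillate near convergence (two particles
exchanging pixels). When an acceptance exactly reverses one of the last
W = 10 iterations, or the energy fails to decrease over W iterations, the
acceptance fraction is halved (floor 0.05) — only the best
⌈fraction·count⌉ selections execute. A relabeling executed at least 4
times in each direction is additionally frozen for the rest of the run.
The freeze guarantees termination even where distributed ΔE estimates are
inexact near block boundaries; it fixes the oscillating pixels at one of
their two alternative pixelations of the contour, which is also where the
few sequential/distributed pixel differences live.

## Distributed layer

The distributed algorithms run on a simulated message-passing runtime:
one `SubDomainState` per rank, explicit message queues, and delivery only
at round boundaries, so rank execution order within a round cannot affect
any output (tests shuffle it). Collectives (statistics reduction, hot
flags, convergence) are explicit reductions. A real transport could be
substituted without changing the algorithms; the simulation is what makes
the layer testable at desk scale.

* **Decomposition.** Cartesian blocks only (remainder pixels to the last
  block per axis), checkerboard-colored so face-adjacent blocks differ.
  Ghost width g = max(R_κ, R if PS else 0) + 1. For the PS model the
  stored frame is widened to 2R+1 so owned-pixel ΔE values are exact;
  with the nominal width, window clipping makes cross-boundary estimates
  inconsistent between ranks, which can prevent termination. Cells beyond
  the image border carry a −1 sentinel so local enumeration treats them
  exactly like the sequential driver treats out-of-grid neighbours.
* **Label initialization.** Each rank labels its local FG components
  r + 1 + k·P (no label used twice), then boundary labels relax to the
  pairwise minimum across block faces until a global fixed point. The
  result equals a global flood fill of the FG mask up to bijection; the
  minimum advances one per-block fragment per round. Both drivers
  normalize their initial labels this way, which makes a 1×1 distributed
  run bit-identical to the sequential driver (labels, traces, iteration
  counts).
* **Contour propagation.** Per iteration each rank builds its local move
  graph over owned + ghost pixels and splits it into interior sub-graphs
  (all pixels owned) and boundary sub-graphs (touching non-owned pixels).
  Black ranks resolve their boundary sub-graphs first — skipping
  sub-graphs with no owned pixel, and selecting only moves on pixels they
  own or their white face-neighbours own — and ship the decisions. White
  ranks accept received decisions verbatim, skip sub-graphs a received
  decision already resolves, and otherwise select their best own-pixel
  move that shares no pixel with a received decision's move or its face
  neighborhood. Interior sub-graphs are resolved independently by
  everyone. Selections are capped by the rank's local acceptance
  fraction, routed to the pixel owner, and executed in global
  (ΔE, pixel, target) order with re-validation. When two diagonal black
  ranks decide the same corner pixel from their truncated views, the
  better (ΔE, pixel, target, sender) decision wins deterministically.
* **Region re-labeling.** After execution, owned boundary-shell pixels
  whose label was rewritten by a fusion or split event become hot
  particles (pixel, old, new); ordinary moves travel with the regular
  ghost exchange instead. Received hot particles seed flood fills over the
  receiver's pixels still carrying the old label; fusions always lower
  labels (min-label rule), split events replace exactly the matching
  component. Re-activation back toward the face an identical event
  arrived from is suppressed, so a label change crossing an r-block chain
  takes exactly r−1 rounds and untouched regions generate no traffic.
  A global hot-flag reduction terminates the loop.
* **Energy trace.** The global energy is reduced every iteration from
  per-rank owned-pixel data terms plus boundary pairs counted once (owned
  by the lexicographically smaller pixel); for PS each rank's window maps
  cover its owned pixels exactly, so the distributed trace is exact, not
  approximated.

Breaking boundary sub-graphs at block boundaries changes the order in
which moves are discovered, so distributed runs may follow a different
energy path and typically converge in fewer iterations; the benchmark
suite quantifies the resulting differences (worst-case final-energy and
trace differences, differing pixels after label matching).

## Initializers

* `init_bubbles` — axis-uniform grid of disk/ball seeds at cell centers.
* `init_local_maxima` — Gaussian-blur the image (width σ), seed a ball at
  every strict local maximum over the full neighborhood; a flat plateau
  seeds once at its lexicographically smallest pixel and must be strictly
  above its surrounding ring (a constant image yields no seeds);
  overlapping seeds merge. Default seed radius 3 px.
* `init_threshold` — fixed/Otsu/Li threshold; face-connected mask
  components become regions.
* `init_bounding_box` — one region filling the image eroded by a margin.

## Synthetic workloads

`make_unit_cell` places non-overlapping ellipsoids of pairwise distinct
intensities on a uniform background, either all clear of the cell boundary
or with a fraction (default 25%) wrapped across the periodic boundary;
`tile_periodic` concatenates cells so wrapped objects become contiguous
across seams; `add_noise` adds Gaussian (clipped at 0) or mean-preserving
Poisson noise. Defaults emulate fluorescence microscopy on an 8-bit-like
scale: background 10, object intensities sampled without replacement from
40 evenly spaced levels in [100, 250], semi-axes U[4, 10] px in 2D and
U[3, 8] px in 3D, noise σ = 5. The intensity floor keeps every object in
the growth regime of the length prior (flat-front growth needs squared
contrast > 2λ on the normalized scale); `min_gap` controls object
separation for workloads that require one blurred-intensity maximum per
object. The generator produces exact ground-truth labels; it does not
emulate point-spread functions, intensity shading inside objects, or
autofluorescence, so passing benchmarks demonstrate algorithmic agreement
and recovery on well-contrasted data, not robustness to real microscopy
artifacts.

## Benchmark conditions

The agreement suite (`drcseg.benchmarks`, `scripts/acceptance.py`) uses
128² images with 8–12 objects, Gaussian noise σ = 5, normalized by 255 so
that λ = 0.04, θ = 0.02 operate on the [0, 1] intensity scale; PC runs
(10 seeds) start from local maxima (σ = 5) of the clean intensity field —
seeding on the noisy field plants spurious background seeds whose frozen
noise blobs measure initialization artifacts rather than the distributed
algorithms — and PS runs (5 seeds, β = 0.05, R = 8) start from Li
thresholding, the natural initialization for noisy data under the PS
model (ball seeds are marginal there because the background's local means
can model unclaimed objects). Distributed grids are (2, 2) and (2, 4).
Region-discovery checks use clean 96² images with k = 2..10 objects,
semi-axes U[4, 8] and min_gap 6 so each object carries exactly one blurred
maximum. Degenerate-equivalence checks add 64³ 3D fixtures with 8
objects. All problem sizes are deliberate desk-scale choices: they keep
the full suite in the minutes range on one CPU while still exercising
objects that straddle every block boundary.

## Numerical choices and limitations

* Coordinates are 0-based, (z, )y, x row-major; BG connectivity in 3D is
  26; labels are arbitrary positive integers, never recycled.
* Ties break everywhere by (ΔE, lexicographic pixel, target label
  ascending) — required for sequential ≡ distributed(1×1) bit-equality.
* Poisson log clamp 1e−8; PS window maps use FFT convolution above 4096
  pixels (counts are rounded back to integers), direct summation below.
* θ compares raw region-mean intensity differences, not noise-normalized
  ones.
* The PS fusion admissibility test uses global region means from the
  sufficient statistics (local means at the touching site would require a
  site argument; the global test is a conservative, symmetric stand-in).
* Single move per maximal connected sub-graph per iteration — the
  conservative reading of rank-based selection; sparse conflicts make
  this equivalent to mass acceptance in practice.
* The dependency graph is built over improving moves only (ΔE < 0);
  non-improving moves could only merge sub-graphs and are never selected.
* Out of scope: real MPI transport and wall-clock scaling, master/slave
  baselines, GPU acceleration, shape priors, Sobolev gradients,
  deconvolving image models, anisotropic voxel spacing.
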