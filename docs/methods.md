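# Methods

## Model and pipeline

somscape clusters a features × patterns matrix by training an emergent
self-organizing map (ESOM) on reduced-dimension pattern fingerprints and
segmenting the trained map's U-Matrix image. "Emergent" means the lattice
carries many more neurons than there are patterns, so clusters appear as
spatial regions of the map rather than as individual prototype neurons; a
helper (`suggest_lattice_size`) proposes ≥ 5 neurons per pattern when the
user does not fix the lattice dimensions, but the user's values always win.

### Dimensionality reduction

`truncated_svd` computes the top-k singular triples of the matrix via a
full LAPACK SVD (problem sizes here never justify iterative solvers) and
fixes signs so the largest-magnitude entry of each left singular vector is
positive, making results reproducible across backends. Centering (subtract
the per-feature mean across patterns) is **on by default**: the linear map
initialization spans directions around the data mean, and the fingerprint
space is then exactly the PCA-scores space. `--no-center` disables it for
data already centered or deliberately offset. Default k is
min(10, n_features, n_patterns).

### Map initialization

Neuron (r, c) starts at `a_r·σ₁·e₁ + b_c·σ₂·e₂` in fingerprint
coordinates, with a_r, b_c spanning [−1, 1] linearly across rows/columns:
a flat sheet covering ±1 singular-value-unit of the two dominant data
directions. `train_flsom` additionally shifts this sheet to the fingerprint
mean, which is a no-op under default centering but makes training exactly
equivariant under global translation of the fingerprints (verified by a
property test).

### FLSOM training schedule

Each epoch is a standard batch update: BMUs are computed once from the
pre-update lattice, each neuron's target is the Gaussian-neighborhood
weighted mean of all patterns (grid-Euclidean distance, planar rectangular
topology), and the new weight blends old and target by the learning factor
α. Neurons receiving negligible neighborhood mass (< 1e-12) keep their
weights rather than dividing by ~0.

The annealing schedule treats the quantization error as the temperature.
With relative improvement r = (QE_prev − QE_curr)/QE_prev:

| phase | condition | σ update | α update |
|---|---|---|---|
| productive | r ≥ 0.01 | σ·0.90 (floor 1.0) | unchanged |
| slow | 0 ≤ r < 0.01 | σ·0.98 (floor 1.0) | α·0.9 (floor 0.05) |
| worsening | r < 0 | unchanged | α·0.5 (floor 0.05) |

Training stops when |ΔQE| < 1e-4 (user-settable) or after 200 epochs.
Defaults: σ₀ = max(rows, cols)/2, α₀ = 1. The schedule is isolated behind
`adapt_learning` so an alternative can be swapped without touching the
training loop. The whole procedure is deterministic — there is no random
initialization and BMU ties break by lowest row-major index — so identical
configurations give bit-identical results.

### U-Matrix

We use the U-height variant: one value per neuron, the mean weight-space
distance to its 8-neighborhood (fewer neighbors at borders). This keeps the
image the same shape as the lattice, so a segmentation label per pixel *is*
a label per neuron, and pattern assignment via BMU coordinates is exact.
The 8-neighborhood gives smoother boundary ridges for the edge detector
than the 4-neighborhood. Rendering min-max normalizes heights and (by
default) inverts, so plateaus of similar neurons are light and boundaries
dark; a constant-height map renders uniformly light. PNG output quantizes
to 8 bits with round-half-even.

### Edge detection

The Canny pass runs on the dissimilarity field (1 − rendered image), so
boundary ridges are gradient maxima. Steps: separable truncated Gaussian
blur (σ = 1.0, kernel radius 2, reflect borders) → Sobel gradients →
non-maximum suppression with the gradient direction quantized to
{0°, 45°, 90°, 135°} → hysteresis with thresholds expressed as fractions
(defaults 0.1 / 0.3) of the maximum gradient magnitude, keeping strong
pixels and any weak pixel 8-connected to one. These four values are the
map's tuning parameters and can be changed per `segment` run without
retraining.

Numerical conventions worth stating: NMS compares strictly (>) against the
neighbor in the positive quantized direction and non-strictly (≥) against
the other, so a perfectly symmetric two-pixel ridge thins to a single line
deterministically; out-of-image neighbors count as zero magnitude; a
constant image short-circuits to an empty mask.

### Region growing and cluster assignment

Non-edge pixels are flood-filled with 4-connectivity (edges link with
8-connectivity, so a thin diagonal edge still separates regions), labelled
in order of first row-major seed; components below `min_region_size`
(default 2) are demoted to unlabeled, suppressing single-pixel noise
regions. Every pattern joins the region of its BMU cell. A pattern whose
BMU fell on an edge or demoted cell is reassigned deterministically: the
search radius around the BMU grows one cell at a time until labelled cells
appear, and among the regions found, the one whose mean neuron weight is
closest to the pattern's fingerprint wins (ties to the lower label). The
report therefore always covers every pattern; clusters are relabelled
1..m by decreasing membership.

## Synthetic data

`make_gaussian_blobs` draws cluster centers on the radius-`separation`
hypersphere, rejection-resampling until all mutual center distances reach
`separation`, and adds unit-variance isotropic Gaussian noise — so
separation is in units of the noise scale and "well-separated" is
quantitative (the recovery experiments use separation 10, i.e. 10σ between
centers). `make_fragment_matrix` emulates the *shape and sparsity* of a
frequent-subgraph miner's binary fragment × compound output: per-cluster
signature fragment blocks carried with probability 0.8 against a 0.05
background. It does not emulate subgraph semantics (fragment nestedness,
correlated sub-structures), chemistry, or heavy-tailed fragment
frequencies; passing recovery tests on it shows the pipeline separates
block-structured binary data, not that it handles every real mining output.
Both generators are pure functions of their arguments including the seed.

## Verification scale

The oracle-equivalence tests compare the vectorized implementations of the
batch epoch, quantization error, U-heights, Canny mask and region labelling
against independently written double-loop references on 20 seeded instances
each (lattices ≤ 10×10, ≤ 20 patterns, images ≤ 10×12) at 1e-10 absolute
tolerance (mask equality for the image ops). The recovery experiment —
4 clusters, 8 dimensions, 30 patterns per cluster, separation 10, SVD k=4,
30×30 lattice, all defaults, 5 seeds — was chosen as the smallest
configuration that is comfortably in the emergent regime (900 neurons for
120 patterns); the whole suite runs in a few seconds.

## Known limitations

- Segmentation can occasionally split off a tiny satellite region along a
  wall and hand it 1–2 patterns (one of five recovery seeds shows a
  singleton fifth cluster); lowering `--canny-low` or raising
  `--min-region-size` merges such satellites, at the usual
  over-/under-segmentation trade-off.
- The lattice is planar and rectangular; no hexagonal or toroidal
  topologies, no online training, and no projection of new patterns onto a
  trained map.
- The annealing schedule is one concrete realization of "ΔQE adapts the
  learning rate"; other schedules fitting that contract may converge
  differently.
- U-heights (same-size image) rather than the expanded (2r−1)×(2c−1)
  classical U-Matrix; fine structure between neuron pairs is averaged into
  the per-neuron value.
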