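# somscape

Unsupervised clustering and visualization of high-dimensional biological
feature tables with an emergent self-organizing map (ESOM).

Many explorative pipelines in cheminformatics and the omics disciplines end
with the same question: *given a large features × patterns matrix — fragment
occurrences per compound, expression values per sample — which patterns form
groups, and how are the groups related?* somscape answers it with a
six-stage pipeline:

1. **Truncated SVD.** The features × patterns matrix `A` is (optionally)
   column-mean-centered and decomposed; each pattern gets a k-dimensional
   *fingerprint* `y_j = U_k^T (a_j − ā)`, the projection onto the top-k
   singular directions.
2. **Linear map initialization.** A rows × cols neuron lattice is imprinted
   as a flat sheet spanning the first two singular directions, scaled by
   σ₁ and σ₂ — an ordered, data-aligned starting configuration.
3. **FLSOM training.** Batch SOM learning with a Gaussian grid neighborhood
   `h(b, j) = exp(−d²(b, j)/2σ²)` is combined with a simulated-annealing
   schedule: the quantization error `QE = mean_i ‖y_i − w_{bmu(i)}‖` plays
   the role of the temperature, and its change between epochs (ΔQE) adapts
   the neighborhood radius and learning factor. Training stops when
   |ΔQE| falls below a user threshold.
4. **U-Matrix.** Each neuron's U-height is its mean weight-space distance to
   its 8 lattice neighbors; rendered so similar regions appear light and
   cluster boundaries dark.
5. **Edge detection.** A Canny pass (Gaussian blur → Sobel gradients →
   non-maximum suppression with quantized directions → two-threshold
   hysteresis) traces the boundary ridges on the map image.
6. **Region growing.** Non-edge cells are flood-filled into disjoint
   regions; every pattern joins the region of its best matching unit, giving
   a complete cluster report.

Because the lattice has far more neurons than patterns (the emergent
regime), cluster structure appears as geography on the map rather than as
one-neuron-per-cluster coding — and the number of clusters is *discovered*
by the image segmentation, not fixed in advance.

## Worked example

Generate a synthetic dataset of 4 Gaussian clusters (30 patterns each,
8 features, centers 10 noise-units apart), then run the full pipeline on a
30 × 30 lattice with k = 4:

```
$ somscape synth --kind blobs --n-clusters 4 --dim 8 --n-per-cluster 30 \
      --separation 10 --seed 3 -o data
wrote 8x120 matrix to data

$ somscape run data/matrix.tsv --svd-k 4 --rows 30 --cols 30 -o out
trained 33 epochs (stopped by delta_qe); final QE = 0.134702
4 clusters: 1:30, 2:30, 3:30, 4:30
artifacts in out
```

Training converged in 33 epochs when the epoch-to-epoch change of the
quantization error dropped below the stopping threshold (1e-4); the final
QE of 0.135 means patterns sit on average 0.135 fingerprint-units from
their best matching unit — far below the unit noise scale of the data. The
segmentation found exactly the four generated clusters, 30 patterns each.

`out/` then contains:

- `map.png` — the U-Matrix (light plateaus = clusters, dark walls = borders);
- `labels.png` — the segmented regions;
- `clusters.txt` — one block per cluster (`cluster <label>\t<size>`, then one
  pattern id per line);
- `qe_trace.txt` — per-epoch quantization error;
- `manifest.txt` — every resolved parameter as `key=value`; re-running with
  `somscape run --config out/manifest.txt -o out2` reproduces all outputs
  byte-for-byte;
- `model/` — the trained lattice, fingerprints and BMUs as re-loadable
  delimited text.

The map can be re-segmented without retraining — the command-line analogue
of tuning the edge-detection sliders interactively:

```
$ somscape segment out/model --canny-low 0.05 --canny-high 0.2 -o out_seg
```

and `somscape query out/model 12,7 12,8` lists the patterns mapped to
specific cells. Real data enters the same way: a TSV/CSV with feature ids
as rows and pattern ids as columns (`--orientation patterns_as_rows` for
the transposed dialect), optionally with `--names`/`--smiles` side lists
for compound collections.

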