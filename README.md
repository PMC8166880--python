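# tabimg

Convolutional networks need inputs whose spatial arrangement carries
information, but most scientific tables — gene-expression profiles of cell
lines, molecular-descriptor tables of drugs — have no natural feature
order. `tabimg` turns each row of a numeric table into a compact grayscale
image by assigning every feature to a pixel so that **similar features end
up on nearby pixels**, then provides the tooling around that transform: a
layout-quality metric, a synthetic-data generator with known structure, a
two-tower CNN for regression on image pairs, and a command-line pipeline.
It is aimed at practitioners who want CNNs on tabular data (e.g.
drug-response prediction from cell-line and drug profiles) without domain
knowledge or blank-padded projection images.

## The method

For an M×N table, compute the N(N−1)/2 pairwise distances between feature
columns and rank them ascendingly into a symmetric rank matrix **R**
(small distance → small rank, zero diagonal). Do the same for the pairwise
coordinate distances of the N pixels of an N_r×N_c grid (row-major
linearization) to get **Q**. The layout search minimizes

    err(R, Q) = Σ_{i>j} diff(r_ij, q_ij),    diff = |·| or (·)²

over synchronized row/column permutations of R. Each iteration picks the
feature not considered for the longest time (round-robin via a
last-considered vector **h**), finds the swap partner with the largest
error reduction — an O(N) incremental computation touching only the two
affected rows/columns — and accepts the swap when the relative reduction
exceeds `t_swap`. The run stops at `s_max` iterations or when the relative
reduction over a window of `s_con` iterations stays below `t_con`; it
returns the best ordering seen and its error. With `t_swap ≥ 0` the error
trace is monotonically non-increasing; the whole search is deterministic.

Each sample then renders as an image whose pixel p holds the (min-max
normalized) value of the feature assigned to p. Layout quality is
quantified by **local heterogeneity (LH)**: the mean absolute difference
between each pixel and its p×p neighbors, averaged over all full windows —
lower is smoother, i.e. better neighborhood preservation — and layouts are
compared via the reduction percentage `(LH_other − LH_ref)/LH_other·100%`.

## Worked example

```python
import tabimg as ti

spec = ti.BlockStructureSpec(n_samples=200, n_blocks=10, block_size=10,
                             within_block_correlation=0.9, seed=0)
data = ti.generate_block_correlated_table(spec)

grid = ti.ImageGrid(10, 10)
R = ti.feature_distance_rank_matrix(data)
Q = ti.pixel_distance_rank_matrix(grid)
result = ti.igtd_optimize(R, Q, ti.IGTDConfig(s_max=3000, s_con=300))
```

Running `examples/01_layout_from_table.py` (the script above) prints:

```
initial error : 7,524,361
final error   : 4,471,815 (40.6% reduction)
iterations    : 648 (converged=True)
```

The identity layout mismatches the pixel ranking by 7.5M summed rank
units; 648 deterministic swaps cut this by 40.6%. Rendering the same
normalized samples under the optimized and under random orderings
(`examples/03_local_heterogeneity.py`) gives

```
 p  lh_mean  lh_sd  lh_mean_other  lh_sd_other  reduction_pct_mean  p_value
 3   0.1433 0.0261         0.2063       0.0419             29.7051      0.0
 5   0.1739 0.0389         0.2045       0.0410             14.6299      0.0
```

— the optimized layout is ~30% smoother than random layouts at the 3×3
neighborhood scale: correlated features were indeed pulled together.

The other examples cover the rank-matrix toys (`02`), the two-tower CNN
architecture and its parameter totals (`04`: 1,307,218 parameters for two
50×50 inputs at stride 1; 2,715,218 for 227×387 + 380×387 inputs at
stride 2), and smoke training on a planted signal (`05`).

## Command line

```sh
tabimg synth table.csv --samples 200 --blocks 10 --block-size 10 --seed 0
tabimg transform table.csv out/ --rows 10 --cols 10
tabimg metrics out/images/images.h5 --p 3 --p 5
tabimg cnn-smoke --out report.json
```

`transform` writes per-sample PNGs (or a lossless HDF5 archive), the
feature-to-pixel ordering CSV, the error trace, an LH summary and a
reproducibility manifest (config echo, input checksum, package version).

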