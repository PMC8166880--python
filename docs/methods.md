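# Methods

## Model and objective

`tabimg` treats layout construction as rank matching. Given an M×N table
X (rows: samples, columns: features) and a target N_r×N_c grid with
N = N_r·N_c pixels, two N×N rank matrices are built:

* **R** — pairwise distances between feature columns (Euclidean by
  default; 1−ρ for correlation structure; 1−Jaccard for binary tables),
  ranked ascendingly over the N(N−1)/2 unordered pairs;
* **Q** — pairwise distances between pixel coordinates (Euclidean or
  Manhattan), pixels linearized row by row, ranked the same way.

Both are symmetric with zero diagonals. The objective is the summed
per-pair discrepancy over the strict lower triangle,
`err(R,Q) = Σ_{i>j} diff(r_ij, q_ij)`, with `diff` absolute (default) or
squared. Working on ranks rather than raw distances makes the objective
invariant to monotone rescalings of either distance and puts feature and
pixel geometry on a common scale.

### Tie handling

Pixel grids produce massive distance ties (all side-adjacent pairs are at
distance 1). Tied distances receive their *average* rank by default,
which keeps the lower-triangle rank sum at K(K+1)/2 for K pairs
regardless of ties and makes R and Q invariant under relabeling of tied
pairs. An `ordinal` mode (ties broken by pair enumeration order) is
available for users who need strictly integer ranks; it is not the
default because it breaks relabeling symmetry. Which rule the original
description of the method intended is unknown; the choice is exposed as
configuration.

### Degenerate inputs

Constant feature columns make 1−ρ undefined; this is a hard error naming
the offending feature, never a silent NaN substitution. Non-finite table
values are rejected at container construction (imputation is an upstream
concern). `err` on matrices of mismatched shape raises.

## The swap search

The optimizer is a deterministic greedy local search over feature swaps
(a swap exchanges two features' pixel assignments — two rows and two
columns of R simultaneously):

1. **Init**: iteration s = 0, e_0 = err(R,Q), h = (−∞, …, −∞),
   ordering k_0 = identity.
2. **Candidate**: n\* = argmin h (the feature unconsidered longest;
   smallest index on ties). Partner l\* maximizes the error reduction of
   the swap (n\*, l\*); the reduction is computed incrementally — only
   rows/columns n\* and l\* change, and the (n\*, l\*) entry itself is
   invariant — in O(N) per candidate pair, O(N²) for the full partner
   scan, verified exactly against full recomputation in the tests.
3. **Accept** iff (e_prev − e_new)/e_prev > t_swap; then the swap is
   applied and h[n\*] = h[l\*] = s, else only h[n\*] = s. With
   t_swap ≥ 0 the trace is monotone; t_swap < 0 permits uphill moves.
4. **Stop** at s = s_max, or once s > s_con when the relative reduction
   against e_{s−s_con} stays below t_con across the whole window. The
   result is the ordering and error of the best iteration.

Determinism: every tie (candidate, partner, best iteration) resolves to
the smallest index / earliest iteration, so no random source exists and
reruns are byte-identical.

The best iteration is taken as the argmin over the full error trace
*including the initial state*: with a negative t_swap the first accepted
move can be uphill, and returning anything worse than the identity layout
would be indefensible; for t_swap ≥ 0 this coincides with the argmin over
iterations 1..s.

Division guards: a zero current error means the rank matching is exact;
the relative-reduction ratios are then undefined, and the run is declared
converged immediately (e_0 = 0 returns the identity ordering untouched).

### Local optima

Greedy 2-opt search is not globally optimal. On planted instances
(R built by shuffling Q, so the global optimum is exactly 0) the search
recovers the optimum universally on small 2-D grids — 200/200 random
shuffles on both 2×2 and 2×3 grids — but stalls in genuine 2-opt local
optima (no single swap improves; verified exhaustively at the stall) on a
substantial fraction of shuffles at larger or one-dimensional sizes:
roughly 27% at 1×6, 33% at 3×3, and 45% at 4×4 over 200 shuffles each.
Exact-recovery claims in the tests are therefore restricted to the small
2-D grids; larger instances are checked against the weaker, always-true
bounds (exhaustive minimum ≤ final ≤ initial error at sizes where N! is
enumerable). Negative t_swap lets some stalled runs escape but is not a
reliable fix and is not used in the default configuration.

## Rendering and normalization

Features are min-max normalized to [0,1] independently per feature across
samples before rendering, so a fixed pixel is comparable across images;
constant features map to 0. Ranking, by default, uses the raw table
(normalization before ranking is available as configuration — whether the
original method ranked raw or normalized values is unstated, and the
choice changes R only through the distance metric). Rendering is a pure
permutation — pixel p of sample m holds feature `ordering[p]` — so the
multiset of pixel intensities equals the multiset of feature values.
PNG export quantizes intensity×255 with half-up rounding (max round-trip
error 1/510); the HDF5 archive is lossless. Figures in the source
literature show small values as bright; since that is a colormap choice,
intensity polarity is left to the renderer, with an `--invert-gray` flag
on the CLI.

## Local heterogeneity

LH is the mean over all (N_r−p+1)(N_c−p+1) full p×p windows of the
average absolute difference between the window center and its p²−1
neighbors. Only full windows enter (the summation limits exclude borders;
no padding). LH is translation-invariant and scales linearly with
intensity scaling; it is computed on normalized-intensity images so that
layout comparisons use identical values. p must be odd and at most the
smaller image dimension. The paired t-test in the layout summary is a
thin scipy wrapper for convenience, not a contribution.

## Synthetic data

The generator emulates the clustered column-similarity of
expression/descriptor tables with a one-factor model per block:
`x_f = noise_sd · (√ρ·z_b + √(1−ρ)·ε_f)` with z_b shared per block and
ε_f independent standard normals. This gives an exact target within-block
correlation ρ (verified by Monte Carlo at M = 1000 within ±0.05),
near-zero between-block correlation, O(M·N) generation, and bit-exact
reproducibility for a fixed seed (mandatory in the API). Real omics
marginals (heavy tails, counts) are deliberately not imitated: passing
tests show the pipeline orders correlated features correctly, not that it
handles real-data marginal pathologies. The default study conditions used
across tests are 200 samples, 10 blocks × 10 features, ρ = 0.9 on a 10×10
grid — a desk-scale problem where the optimizer converges in well under a
thousand iterations.

Planted layout instances (R = Q with shuffled rows/columns) provide
optimizer ground truth with a known zero optimum; the shuffle is returned
so recovery can be checked up to grid automorphisms.

## Two-tower CNN

The regression model for image pairs (e.g. cell-line image + drug image →
response) has one subnetwork per image: three convolution layers with 5×5
kernels, each followed by batch normalization, ReLU and 2×2/stride-2 max
pooling (valid padding everywhere); the tower outputs are flattened,
concatenated and passed through a fully connected head ending in one
linear unit. Convolution stride is 1 for compact 50×50 inputs and 2 for
large inputs (227×387 and 380×387), all other widths unchanged.

The published description fixes the topology and the two trainable-
parameter totals (1,307,218 and 2,715,218) but not the layer widths.
Treating the totals as constraints: the difference between the two
regimes comes only from the first dense layer (tower flatten sizes
4·f₃ + 4·f₃ vs 10·f₃ + 20·f₃ under this topology), forcing
f₃·d₁ = 64,000 for last-conv filter count f₃ and first dense width d₁.
An exhaustive search over conventional configurations then admits exactly
one solution with increasing filter counts and decreasing dense widths:
filters (24, 64, 100), bias-less convolutions (batch normalization
supplies the per-channel shift), dense head 640 → 500 → 125 → 100 → 1.
These are the package defaults and reproduce both totals exactly; other
exact but unconventional solutions exist, so the widths remain
configuration, and the two totals are asserted in the tests as the guard
on this reading. Batch-norm running statistics are buffers, excluded from
the trainable count.

All layers are implemented in numpy with exact forward/backward passes
(im2col convolution, batch-norm with batch statistics in training mode,
argmax-routed pooling gradients), validated by finite-difference gradient
checks. Desk-scale smoke training uses a scaled-down spec (24×24 inputs,
filters (4, 8, 8), 3×3 kernels, one 16-unit dense layer, ~2k parameters)
on 300 synthetic pairs whose target is a linear function of the two
images' mean intensities plus noise: the fitted model must beat the mean
predictor on a held-out split. Targets are centered on the training mean
so the untrained network already matches the mean predictor; Adam with
learning rate 2·10⁻³, batch 64, up to 50 epochs and patience 15 converges
in a few seconds on one CPU. A zero-signal control confirms no spurious
"learning" beyond noise level.

## Defaults and parameters

| Parameter | Default | Meaning |
|---|---|---|
| `s_max` | 30,000 | iteration cap (reference full-scale run, N = 2500) |
| `s_con` | 500 | convergence window length |
| `t_con` | 10⁻⁶ | relative-reduction convergence threshold |
| `t_swap` | 0 | acceptance threshold; ≥ 0 ⇒ monotone trace |
| `diff_fn` | absolute | per-pair discrepancy |
| metrics | Euclidean/Euclidean | feature and pixel distances |
| grid | 50×50 | reference image size for 2500 features |
| LH `p` | 3 (CLI summary: 3,5,7,9) | neighborhood side length |

Tests and examples run the optimizer at N ≤ 100 with s_max 1,000–3,000
and s_con 100–300: at these sizes the error plateaus within a few hundred
iterations, so the full-scale budgets would only add no-op iterations.
The final result is insensitive to these budgets once the plateau is
reached.

## Known limitations

* Greedy 2-opt layout search has local optima (quantified above); no
  restarts or annealing are provided beyond negative `t_swap`.
* Missing values are rejected, not imputed.
* One grayscale channel per table; no multi-modal stacking into RGB.
* LH compares layouts of the *same* data; absolute LH values depend on
  the normalization convention and are not comparable across datasets.
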