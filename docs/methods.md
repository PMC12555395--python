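# Methods

## Problem and approach

Point-level organ segmentation of plant scans is hard for two structural
reasons: the discriminative geometry is multi-scale (a stem is a thin tube
whose radius is 1–2 % of the plant's extent, while a leaf is a broad bent
surface), and the organ boundaries are smooth (the stem grades into the
petiole and the petiole into the blade).  The network therefore combines a
local operator — per-point kNN graph convolution over difference edges,
which reads the micro-geometry — with a global operator — self-attention
over all points, which supplies plant-level context — and fuses them with
a residual enhancement.

## The model, block by block

**Pose alignment.**  A learned 3×3 transform (predicted by a small
graph-conv + attention trunk, an MLP to 1024 channels, max-pool, and MLPs
512 → 256 → 9) multiplies the input coordinates (row-vector convention).
The final 9-unit layer is zero-initialized and the flattened identity is
added, so the untrained network applies exactly the identity; without this
the random transform at step 0 destroys the geometry.  The matrix is
unconstrained (it can rotate, shear and scale).

**Graph creation block.**  Neighborhoods are scored with squared Euclidean
distance (cheaper than Euclidean, same ordering).  Alternative scores are
available for the design-space harness: Pearson and cosine dissimilarity
(1 − similarity, with a defined fallback of dissimilarity 1 for
zero-norm/zero-variance rows so no NaN can arise), and weighted blends
w·d²_norm + (1−w)·(1−cos) with d² max-normalized per cloud so both terms
are dissimilarities on one scale.  Each point keeps itself plus its k−1
nearest neighbors (so k counts the center); distance ties break by
ascending point index, which makes selection fully deterministic and
testable against a brute-force sort.  Edge features are the raw difference
vectors e_ij = x_j − x_i.  The k rows [x_i ‖ e_ij] pass a shared linear
map and ReLU, and an elementwise max over the k rows gives the new point
feature.

Two numerical choices matter here.  First, pairwise distances use the
matrix identity ‖x‖² + ‖y‖² − 2x·y, clamped at zero with the diagonal
forced to exactly zero, and a test pins the identity to the definitional
sum of squares.  Second, the concatenated rows are batch-normalized per
channel before the shared conv (and its output normalized again before the
ReLU).  The input normalization is load-bearing: on unit-sphere clouds the
edge features live at organ-radius scale, one to two orders of magnitude
below the center coordinates they are concatenated with, so without it the
edge pathway's weights receive proportionally tiny gradients and the
short-schedule training plateaus ~8 accuracy points lower.  The bare
conv+ReLU+max form remains available (`GraphBlockParams(normalize=False)`)
and is what the algebraic unit tests exercise.

**Self-attention block.**  Queries and keys share one projection W_qk of
width C/4 (so the score matrix QKᵀ is symmetric), values use a full-width
W_v, and the softmax normalizes each query row over the keys — the only
axis choice under which the weight matrix A is row-stochastic, which is
what makes the residual interpretation work: (I − A) applied to features
annihilates point-constant inputs, exactly like a combinatorial graph
Laplacian D − E with row-normalized adjacency.  No 1/√d score scaling is
applied; the 4× projection reduction is the stabilizer.  The block output
is LBR(F_in − F_sa) + F_in with LBR = linear + batch-norm + ReLU.  For
comparison harnesses there are an unshared-projection variant ("general")
and standard 4- and 8-head multi-head variants (per-head C/h projections,
concatenation, output projection).

**Head.**  Layer features are concatenated, fused by a shared
linear+BN+ReLU to 1024 channels and max-pooled into one global vector,
which is broadcast back to every point.  Each point's
[aligned xyz ‖ F¹..F^L ‖ global] passes linear(512) → dropout →
linear(256) → dropout → linear(P); argmax (lowest index on ties) gives the
label.  MLPs outside the graph block follow the point-network convention
linear + batch-norm + ReLU; with bare linears the prescribed lr = 0.1
diverges within one step.

**Batch normalization semantics.**  Statistics are taken per channel over
all points of the batch during training and running averages (momentum
0.1) are used in eval mode, which makes evaluation deterministic —
the determinism contract all tests rely on.

**Dynamic vs static graphs.**  By default each GCASM layer recomputes its
kNN graph on its own input features (`graph.space = features`); a static
alternative reuses the aligned coordinates (`coords`).  With one layer the
two coincide, since the first layer's input features are the coordinates.

## Tunable parameters

| parameter | default | meaning / why |
|---|---|---|
| `k` | 30 | local graph size incl. center; the sweet spot between detail and smearing for 2048-point clouds |
| `channels` | (64, 64, 64) | per-layer widths, the lineage convention; gives ~1.9 M parameters, the order of magnitude such models report (printed counts for the original are internally inconsistent, so exact replication is not targeted) |
| `global_dim` | 1024 | global feature width |
| `dropout_rate` | 0.5 | the common default for segmentation heads |
| `attn.qk_scale` | 4 (fixed) | query/key width reduction |
| `data.n_points` | 2048 | random subsample per cloud |
| `data.train_fraction` | 0.8 | dataset split |
| lr schedule | 0.1 × 0.5^⌊e/20⌋ | step decay; lr(45) = 0.025 by this rule |
| noise σ | 0–0.08 | Gaussian coordinate noise, in normalized units (after unit-sphere scaling), where such σ values are meaningful |

Coordinate normalization (centroid-centering + unit max-norm) is the
dominant convention for fixed-size segmentation pipelines and is exposed
as `none | center | unit_sphere`.

## Synthetic plants

The generator emulates greenhouse scans of tomato/pepper-like plants in
relative units (stem height ≈ 1):

* **Stems** are cubic-spline axes — a vertical main axis with smooth random
  lateral wander (amplitude 0.12) plus branches leaving at 25–55° — swept
  by a circular cross-section of radius 0.02, tapering by 40 % toward the
  tip.  Surface points are sampled area-proportionally.
* **Leaves** (6 by default) attach along the stems via a thin petiole tube
  (radius 0.005, length 25 % of the blade) ending in a parabolically bent
  ellipse (length 0.35, width 0.18).  The petiole carries the leaf label
  and is geometrically a thin tube like the stem — deliberately keeping the
  stem-to-leaf transition ambiguous, which is where real segmentation
  models err.
* **Soil**, when present, is a jittered plane patch under the plant.
* **Labels** follow the generating organ, except inside a junction blend
  zone (radius 0.08 × leaf length around each attachment) where they
  follow the nearest organ surface, producing the hard boundary points.
  A stored noise-free reference sampling of every generating surface makes
  this auditable: a test checks ≥ 99 % agreement between emitted labels and
  an independent nearest-surface relabeling outside the blend zone.
* **Density gradient** > 0 re-weights sampling by exp(g·height), emulating
  canopy-heavy scans; surface jitter (σ = 0.002) emulates scanner noise.

What the generator does **not** emulate: self-occlusion by line-of-sight
(every surface is sampled, merely unevenly), multi-plant scenes,
serrated/compound leaf outlines, and sensor-specific artifacts (stripes,
ghost points).  Passing tests on these plants therefore demonstrate that
the pipeline learns and respects thin-vs-flat geometry and junction
ambiguity, not that it matches any particular scanner's error profile.

## Desk-scale reference experiment

Full-size training (2048 points, three 64-channel layers, 200 epochs) is a
GPU-scale job, so the package defines a scaled-down counterpart
(`gcassn.experiments`): 32 two-class plants (no soil) of 512 points,
split 24/8; one 32-channel GCASM layer with k = 10; fuse width 512 and
head (256, 128); 30 epochs of the unchanged reference optimizer recipe.
The Trans-net is omitted at this scale — a learned pose warp needs long
schedules to pay off and measurably destabilizes a 30-epoch run — and the
plants are generated in a canonical pose, so alignment is not the
bottleneck being tested.  Across seeds this reaches ~91–93 % held-out
point accuracy (~82–84 % mIoU); random point-dropping of 25/50/75 % of
points degrades accuracy gracefully, and Gaussian noise degrades it more
steeply than the full-size model reports on real data, as expected for a
reduced model trained on 90 optimizer steps.

A note on the discriminability ceiling: a random-forest probe on
hand-crafted multi-scale eigenfeatures reaches ~0.91 on the same data, so
the network's ~0.92 means it has essentially saturated what 512-point
clouds of these plants support; the residual errors sit at petioles and
junctions, mirroring the error anatomy reported for real scans.

## Design choices in open territory

* The raw soil label code 3 maps to contiguous internal id 2; contiguous
  ids are required for class indexing and the map is user-configurable
  (whether "3" is a typo for "2" in the source data is unknowable here).
* Per-class accuracy uses the standard (TP+TN)/total; the source
  formula's denominator is not a probability and was treated as a typo.
* mIoU excludes classes absent from both truth and prediction
  (`metrics.absent_class = exclude | score_one`); pooled (micro) confusion
  across a test set, the convention for point-level mIoU.
* Deficit sampling (cloud smaller than the target size) pads with
  replacement rather than erroring, so small synthetic clouds work.
* Cross-entropy is unweighted; class weighting exists but is off.
* Degenerate inputs are defined, not NaN: all-coincident clouds normalize
  to zeros; zero-norm rows under cosine score dissimilarity 1; an
  all-zero confusion matrix is an error.

## Known limitations

* Attention is dense (N×N); memory grows quadratically in points, which is
  fine at 2048 points but the reason the desk-scale runs use 512.
* The numpy implementation is single-threaded BLAS-bound; it reproduces
  the architecture's semantics exactly but not GPU training throughput,
  so full-size 200-epoch runs are out of scope.
* kNN is exact brute force by design (the selection contract is part of
  the method); no approximate neighbor search is provided.
* The 3×3 transform is unconstrained; no orthogonality regularizer is
  applied (none is specified for this architecture).
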