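# Methods

## Problem and data model

The task is per-point classification of a plant point cloud into three
organ classes, encoded `flower=0, leaf=1, stem=2` everywhere in the
package.  A whole plant is far larger than one network input, so it is
first partitioned into spatially coherent blocks of roughly
`target_points` points (default 2048), each block resampled to exactly the
network input size, centred on its centroid and scaled to unit radius
before inference.  Centring/scaling is an explicit pipeline step — file
I/O never modifies coordinates, so round trips are lossless (binary PLY is
bitwise, ASCII to ~1e-6).

### Block splitting

No canonical algorithm exists for "blocks of consistent size whose
internal structure stays complete", so the splitter is defined as:

1. voxel-grid partition at an edge length found by bisection so the median
   occupied-voxel population is within [0.75, 1.5]× the target;
2. greedy merging of adjacent (26-connected) under-populated voxel groups
   — merges that only improve size consistency respect a 1.5× target cap,
   merges required to reach `min_points` (default `target/4`) ignore it;
   an isolated fragment with no adjacent group merges with the
   nearest-centroid group;
3. recursive median-plane splitting (longest axis, stable sort) of any
   group above `2 × target`.

The result is a partition (every source point in exactly one block,
verified by index bookkeeping) with all block sizes in
`[min_points, 2·target]`.  Plants not larger than 1.5× the target pass
through as a single block, as do plants below `min_points` (with a
warning).

### Resampling

Blocks with at least `n_points` points are subsampled uniformly without
replacement; smaller blocks keep every point once and draw the remainder
with replacement.  Labels travel with their points; the expected label
distribution is preserved (checked by a pooled chi-square over 100 seeded
resamples).  Everything is driven by an explicit seed.

## Geometry primitives

All three primitives are exact brute-force computations with fixed
tie-breaking, so the whole forward pass is bit-for-bit reproducible:

* **Farthest point sampling** — greedy max-min with an explicit
  `start_index` (default 0, surfaced in config); ties go to the lowest
  index.  The selected *coordinate set* is invariant to input permutation.
* **Ball query** — closed ball (≤ radius), neighbours ordered
  nearest-first with ties by lowest index, the centre always a member;
  ragged neighbourhoods are padded with the centre index plus a validity
  mask so symmetric pooling ignores the padding.
* **Feature grouping** — pure gather; padded slots carry the centre's
  feature; gradients flow back through the gather.

## Position code

Each neighbourhood is summarised by a relative code (RPC) and an absolute
code (APC).  The RPC applies a 2-layer MLP (3→32→C_r by default) to every
centre-minus-neighbour offset and max-pools over valid neighbours — the
symmetric-function device that makes the code invariant to neighbour
ordering; because offsets cancel translations algebraically, the RPC
branch is exactly translation-invariant (bitwise on dyadic-rational
coordinates, to ~1e-12 on arbitrary floats).  The APC maps the centre's
block-local coordinates through an independent MLP; the two MLPs do not
share weights because they consume different semantics (offsets vs.
coordinates).  Whether the centre's absolute coordinate also belongs
inside the RPC tuple is genuinely ambiguous; the flag
`include_center_in_rpc` (default off) exposes both readings, and the
position tests pin down the invariance consequences of each.

## Network

Per block: every point gets a feature combining a coordinate embedding
(3→32→d_m MLP) with the position code of its own neighbourhood
(`radius_point`).  This per-point geometric feature was a deliberate
design choice after the obvious alternative failed: propagating *class
scores* from k local tokens to all n points cannot express per-point
boundaries (a 96-token partition of 512 points capped single-block overfit
accuracy below 0.8), whereas propagating fused token *features* and
classifying each point from `[own feature ; token context]` reaches
perfect single-block training MIoU within 200 steps.

* **Global branch (multi-scale grouping)**: FPS picks `m_fps` centres;
  each of three radii yields RPC+APC codes and max-pooled point features,
  concatenated per scale, fused across scales, then refined by a
  self-attention block.
* **Local branch (score-and-select)**: a d_m→32→1 MLP scores every point;
  the top-k (stable sort, ties by lowest index) anchor ball-query
  neighbourhoods whose codes and pooled features concatenate skip-style
  with the anchors' own features.  Selection is hard and
  non-differentiable; multiplying selected features by their scores keeps
  the score map in the gradient path.
* **Fusion**: local tokens attend over global tokens (cross attention),
  then the detection head runs a second cross attention and a pointwise
  stack; fused token features are propagated to all points (nearest
  anchor, or inverse-distance over the 3 nearest — config `upsample`),
  and a final pointwise MLP yields per-point logits.

The three attention modules (self, local-global, cross) expose their
per-head output matrices `F_sa^i`; all of them feed the separation loss.
Attention uses widths `h, d_m, d_k, d_v` with
`W^Q,W^K ∈ R^{h×d_m×d_k}`, `W^V ∈ R^{h×d_m×d_v}`, `W^O ∈ R^{h·d_v×d_m}`;
LayerNorm and the feed-forward stack can be bypassed for analytic tests.
Layer counts per branch are one attention block each by default
(config-exposed); the high-dimensional feature extractor is shared across
scales (a per-scale variant sits behind `shared_highd=False`).

## Objective

`separation_loss` flattens each head matrix and returns
`−(1/h²) Σ_{i≠j} |⟨f_i,f_j⟩| / (‖f_i‖‖f_j‖)` over ordered pairs — the h²
normaliser reads the formula's count as the head count, the only reading
under which the quantity is the average pairwise cosine and lands in
`[−(h−1)/h, 0]` (lower bound iff all heads pairwise parallel, 0 iff all
pairs orthogonal).  The absolute value penalises anti-parallel heads the
same as parallel ones.  A head with numerically zero norm contributes 0 to
its pairs (epsilon-guarded, logged).

The combined objective is `CE + loss_scal · (−separation)`: the term
enters as a non-negative penalty so that gradient descent *disperses* the
heads.  Entering the raw (negative) value instead would reward head
collapse — the descent demonstration and the ablation direction both pin
the sign.  The separation term is averaged (not summed) over the
attention modules so `loss_scal` keeps one meaning regardless of
architecture depth.  `loss_scal` defaults to 1.0.

Cross-entropy defaults to the standard categorical form (softmax vs
one-hot, mean over points); a literal per-class binary-sum variant is
available as `mode="literal"` for auditability.  Both vanish on a perfect
one-hot prediction.

## Metrics

Per-class one-vs-rest tallies come from the 3×3 confusion matrix
(scikit-learn); `IoU_c = TP/(TP+FP+FN)` is the set intersection-over-union
and MIoU its mean over classes with non-empty union (absent classes are
excluded with a warning; all-absent raises).  A `literal` variant with
denominator `TP+FP−FN` is retained for auditability only — it can exceed
1 or divide by zero and is never used by the pipeline.

## Synthetic plants

The generator produces the structure that makes the task hard, not
botany: stems are random cubic-spline tubes (5 jittered control points,
tube radius 0.012 in plant units where the main stem is O(1) long);
leaves are bent elliptical patches (half-width ratio 0.5, quadratic bend)
attached to stems; flowers are unions of 5–8 tilted petal patches at stem
tips.  Default composition (3 stems, 5 leaves, 3 flowers at 100–180
points per organ) yields ~1500-point plants at roughly 46% leaf / 29%
stem / 25% flower — interwoven but balanced enough that every class is
learnable.  `interleave ∈ [0,1]` linearly blends between the natural
attached layout (1: organ bounding boxes overlap) and a well-separated
grid layout (0: pairwise margins exceed twice the noise level); default
0.7.  Isotropic Gaussian noise (default sd 0.004) is added last.  All
geometry derives from one seeded generator, and a dataset manifest records
every per-plant seed and spec so regeneration is bitwise.

What the generator does **not** emulate: sensor artefacts (view-dependent
occlusion, range noise anisotropy), petioles and branching topology
beyond one level, self-similar foliage density, or the scale and
point-density statistics of real scan datasets.  Passing the benchmark therefore demonstrates
that the architecture, losses and pipeline work end to end on interwoven
thin/flat/clustered geometry — not that the trained weights transfer to
real scans.

## Training pipeline

Adam with initial learning rate 1e-3 and batch size 16 over 2048-point
blocks are the protocol defaults.  Gradients are accumulated across each
batch's blocks, one Adam step per batch; per-epoch history records the
loss components and validation MIoU; the best-by-validation-MIoU state is
kept (constant learning rate, early stopping with patience 20 of 100
epochs by default — no schedule is prescribed, so none is imposed).
Non-finite loss aborts with a JSON dump of the offending batch.
Checkpoints are single `.npz` files embedding the full run config.  Two
runs with the same config and seed produce identical histories; the
history deliberately contains no wall-clock fields.

## Scaled benchmark and ablation

The desk-scale experiment (`plantseg3d.experiments`) uses 30 default-spec
plants split 25/5 by whole plant, 512-point blocks, and a reduced model:
d_m=64, h=4, d_k=d_v=16, m_fps=48, k_local=96, radii (0.12, 0.25, 0.5) of
the unit block radius, k_max=12, inverse-distance-3 upsampling, batch 4,
learning rate 2e-3, at most 30 epochs with patience 8.  These sizes are
the package's chosen desk-scale operating point: small enough to train in
minutes on one CPU, large enough that the held-out task is non-trivial.
The ablation harness re-runs the identical dataset and seed with
components switched off (`full`, `no_rpc`, `no_sep`, `baseline` = both
off), reporting held-out MIoU and the mean absolute pairwise head cosine
at convergence.  The claims checked are directional — with the separation
loss the head cosine at convergence is lower than without on the same
seed — plus an absolute held-out MIoU floor of 0.70 for the full model on
synthetic plants.

## Numerical choices

* float64 throughout; gradients validated against central finite
  differences (1e-4 relative for the separation loss, 1e-5 for the engine
  ops).
* Softmax is max-shifted; LayerNorm epsilon 1e-5; cosine denominators
  guarded at 1e-12; masked max-pools fill invalid slots with −1e30 (the
  centre slot is always valid, so pools are never empty).
* Ties everywhere resolve to the lowest index (FPS, ball query ordering,
  top-k, nearest-anchor upsampling), making every path deterministic.
* Exact translation invariance of the RPC is a statement about the
  algebra; tests assert it bitwise on dyadic-rational coordinates (where
  float addition is exact) and to 1e-12 atol on arbitrary floats.

## Known limitations

* Brute-force neighbourhood search is O(N²) per block — appropriate at
  desk scale, not for million-point scans.
* Hard top-k with score multiplication is a coarse gradient path; anchors
  can drift slowly early in training.
* The literal IoU and binary cross-entropy variants exist for audit only.
* Reported benchmark numbers are for synthetic plants; no claim is made
  about real scanner data.
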