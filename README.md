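# plantseg3d

Organ-level semantic segmentation of 3D plant point clouds.

Plant phenotyping starts from knowing which points of a laser- or
photogrammetry-scanned plant belong to which organ.  That segmentation is
unusually hard: stems are thin tubes winding through the whole scene,
leaves are broad and curved, flowers are dense clusters, and all three
interweave and occlude each other.  `plantseg3d` labels every point of a
plant cloud as **flower (0), leaf (1) or stem (2)** with a two-branch
attention network, and ships a procedural generator of labelled synthetic
plants so the entire pipeline trains and evaluates on one CPU with no
external data.

## The model

Each ~2048-point block of a plant is processed by two branches built from
multi-head attention

```
Multihead(Q,K,V) = (F_sa^1 ⊕ … ⊕ F_sa^h) W^O
S     = LayerNorm(X + Multihead(X, Y, Y))
A(X,Y)= LayerNorm(S + Φ(S))
```

where `F_sa^i` is head *i*'s output and Φ a pointwise feed-forward stack.
The **global branch** samples m centres by farthest point sampling and
groups their neighbourhoods at three radii (multi-scale grouping); the
**local branch** scores every point with a learnable map and keeps the
top-k as local anchors.  Both branches encode every ball-query
neighbourhood with a two-part **position code**: relative offsets
(centre − neighbour, exactly translation-invariant, order-invariant via a
max-pooled MLP) concatenated with the centre's absolute coordinates through
a second MLP.  A cross-attention detection head fuses local and global
tokens, and a pointwise classifier produces per-point class scores.

Training minimises

```
Loss = CrossEntropy + loss_scal · SeparationPenalty
SeparationLoss = −(1/h²) Σ_{i≠j} |⟨f_i, f_j⟩| / (‖f_i‖‖f_j‖)   ∈ [−(h−1)/h, 0]
```

with `SeparationPenalty = −SeparationLoss`, the mean absolute pairwise
cosine between flattened head features, averaged over all attention
modules.  Minimising it pushes the attention heads apart, so different
heads attend to different regions instead of collapsing onto the same one.
Evaluation uses per-class IoU (`TP/(TP+FP+FN)`) and their mean (MIoU).

## Worked example

`examples/train_segment.py` generates 8 synthetic plants, splits them by
whole plant, trains the reduced (d_m=64, h=4, 512-point) model for 8 epochs
and evaluates the held-out plants:

```
18 training blocks, 2 held-out blocks
  epoch 0  total 1.466  ce 1.325  sep -0.141  val MIoU 0.147
  epoch 1  total 1.039  ce 0.957  sep -0.082  val MIoU 0.158
  ...
  epoch 6  total 0.652  ce 0.632  sep -0.020  val MIoU 0.509

held-out metrics:
  IoU flower  0.603
  IoU leaf    0.538
  IoU stem    0.384
  MIoU       0.509
```

`total` is the combined objective, `ce` the cross-entropy, `sep` the
separation loss (rising toward 0 as the heads disperse), and the IoU rows
are per-organ intersection-over-union on plants never seen in training.
This is a deliberately small run; the full benchmark below (30 plants, up
to 30 epochs) reaches held-out MIoU ≈ 0.83.  The other example scripts
demonstrate the generator, block preprocessing/I/O, and the
separation-loss mechanics.

A CLI covers the same workflow from the shell:

```
plantseg3d generate --n-plants 11 --seed 0 --out data/
plantseg3d train --train data/train --val data/test --out model.npz
plantseg3d evaluate --checkpoint model.npz --blocks data/test
plantseg3d predict --checkpoint model.npz --input plant.ply --output labelled.ply
plantseg3d ablate --seed 1
```

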