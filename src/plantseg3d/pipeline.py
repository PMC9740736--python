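"""Training, evaluation and prediction orchestration.

``RunConfig`` carries every knob: optimisation defaults follow the adaptive
-moment recipe (Adam, initial learning rate 1e-3, batch size 16, 2048 input
points); epochs, early stopping and the separation-loss weight are exposed.
Training minimises ``cross_entropy + loss_scal * separation_penalty`` over
per-block forward passes with gradient accumulation across each batch, logs
a structured per-epoch history, and keeps the best-by-validation-MIoU
parameter state.  Everything is seeded: two runs with the same config
produce identical histories.

Checkpoints are single ``.npz`` files embedding the full RunConfig, so
``evaluate`` and ``predict`` need no side channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from .blocks import resample_block, split_into_blocks
from .cloud import BlockSet, LabeledPointCloud, center_and_scale, CLASS_NAMES
from .errors import ConfigError, PlantSegError, ValidationError
from .autodiff import Adam
from .io import read_point_cloud, write_point_cloud
from .losses import combined_loss
from .metrics import ConfusionCounts, confusion_counts, iou_miou
from .network import ForwardResult, ModelConfig, SegmentationModel

__all__ = ["RunConfig", "TrainResult", "MetricsReport", "train", "evaluate",
           "predict", "save_checkpoint", "load_checkpoint",
           "mean_abs_head_cosine"]


@dataclass
class RunConfig:
    """Full run configuration (model + optimisation + bookkeeping)."""

    model: ModelConfig = field(default_factory=ModelConfig)
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 100
    loss_scal: float = 1.0
    ce_mode: str = "categorical"
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigError("batch_size and epochs must be positive")
        if self.loss_scal < 0:
            raise ConfigError("loss_scal must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["model"] = ModelConfig.from_dict(d["model"])
        return cls(**d)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class MetricsReport:
    """Per-class IoU + MIoU over a block collection."""

    counts: ConfusionCounts
    iou: np.ndarray
    miou: float

    def to_dict(self) -> dict:
        return {
            "miou": float(self.miou),
            "iou": {CLASS_NAMES[c]: (None if np.isnan(self.iou[c])
                                     else float(self.iou[c]))
                    for c in range(len(self.iou))},
            "counts": {CLASS_NAMES[c]: {"tp": int(self.counts.tp[c]),
                                        "fp": int(self.counts.fp[c]),
                                        "fn": int(self.counts.fn[c])}
                       for c in range(self.counts.k)},
        }

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass
class TrainResult:
    model: SegmentationModel
    config: RunConfig
    history: list[dict]
    best_state: dict
    best_val_miou: float


def _forward_block(model: SegmentationModel,
                   block: LabeledPointCloud) -> tuple[ForwardResult, np.ndarray]:
    normed, _, _ = center_and_scale(block)
    return model.forward(normed.coords), normed.labels


def mean_abs_head_cosine(result: ForwardResult) -> float:
    """Mean absolute pairwise cosine between head features, averaged over
    the network's attention modules (the quantity the separation loss
    drives down)."""
    vals = []
    for hf in result.head_features:
        flats = [h.reshape(-1) for h in hf.stacked.data]
        h = len(flats)
        for i in range(h):
            for j in range(i + 1, h):
                ni, nj = np.linalg.norm(flats[i]), np.linalg.norm(flats[j])
                vals.append(abs(float(flats[i] @ flats[j])) / (ni * nj + 1e-12))
    return float(np.mean(vals))


def _dump_bad_batch(batch, out_path: Path):
    data = [{"coords": b.coords.tolist(),
             "labels": None if b.labels is None else b.labels.tolist()}
            for b in batch]
    out_path.write_text(json.dumps(data))


def train(config: RunConfig, train_blocks: BlockSet,
          val_blocks: BlockSet | None = None,
          log_fn=None) -> TrainResult:
    """Fit the network on labelled blocks.

    Per epoch: shuffle blocks, accumulate gradients over each batch, take an
    Adam step, then score validation MIoU.  Keeps the parameter state with
    the best validation MIoU (training MIoU when no validation set is
    given).  Aborts on non-finite loss with a JSON dump of the offending
    batch.
    """
    if len(train_blocks) == 0:
        raise ValidationError("no training blocks")
    for b in train_blocks:
        if not b.has_labels:
            raise ValidationError("training blocks must be labelled")
    ss = np.random.SeedSequence(config.seed)
    init_seed, shuffle_seed = [int(s.generate_state(1)[0] % (2 ** 31))
                               for s in ss.spawn(2)]
    model = SegmentationModel(config.model, seed=init_seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    history: list[dict] = []
    best_state = model.state_dict()
    best_miou = -1.0
    best_epoch = -1
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(train_blocks))
        ce_sum = sep_sum = tot_sum = 0.0
        n_blocks = 0
        opt.zero_grad()
        for bi, start in enumerate(range(0, len(order), config.batch_size)):
            batch_idx = order[start:start + config.batch_size]
            batch = [train_blocks.blocks[i] for i in batch_idx]
            opt.zero_grad()
            scale = 1.0 / len(batch)
            for block in batch:
                result, labels = _forward_block(model, block)
                breakdown = combined_loss(result.logits, labels,
                                          result.head_features,
                                          loss_scal=config.loss_scal,
                                          ce_mode=config.ce_mode)
                if not np.isfinite(breakdown.total_value):
                    dump = Path("scratch") if Path("scratch").is_dir() \
                        else Path(".")
                    dump_file = dump / f"bad_batch_epoch{epoch}_batch{bi}.json"
                    _dump_bad_batch(batch, dump_file)
                    raise PlantSegError(
                        f"non-finite loss at epoch {epoch}, batch {bi}; "
                        f"offending batch dumped to {dump_file}")
                breakdown.total.backward(np.asarray(scale))
                ce_sum += breakdown.cross_entropy_value
                sep_sum += breakdown.separation_value
                tot_sum += breakdown.total_value
                n_blocks += 1
            opt.step()
        # note: no wall-clock entries — the history of a seeded run is
        # bit-for-bit reproducible
        entry = {"epoch": epoch,
                 "cross_entropy": ce_sum / n_blocks,
                 "separation": sep_sum / n_blocks,
                 "total": tot_sum / n_blocks}
        score_blocks = val_blocks if val_blocks is not None and len(val_blocks) \
            else train_blocks
        report = evaluate(model, score_blocks)
        entry["val_miou"] = report.miou
        history.append(entry)
        if log_fn is not None:
            log_fn(entry)
        if report.miou > best_miou:
            best_miou = report.miou
            best_state = model.state_dict()
            best_epoch = epoch
        elif (config.early_stop_patience > 0
              and epoch - best_epoch >= config.early_stop_patience):
            break
    model.load_state_dict(best_state)
    return TrainResult(model, config, history, best_state, best_miou)


def evaluate(model_or_checkpoint, blocks: BlockSet) -> MetricsReport:
    """Accumulate confusion counts over all blocks and report IoU/MIoU."""
    model = model_or_checkpoint
    if not isinstance(model, SegmentationModel):
        model, _ = load_checkpoint(model_or_checkpoint)
    if len(blocks) == 0:
        raise ValidationError("no blocks to evaluate")
    total = None
    for block in blocks:
        if not block.has_labels:
            raise ValidationError("evaluation blocks must be labelled")
        result, labels = _forward_block(model, block)
        c = confusion_counts(result.logits.labels, labels, k=model.config.n_classes)
        total = c if total is None else total + c
    iou, miou = iou_miou(total)
    return MetricsReport(total, iou, miou)


def predict(checkpoint, cloud_path, out_path, fmt: str | None = None,
            seed: int = 0):
    """Label an arbitrary input cloud with a trained model.

    The cloud is block-split, each block resampled to the network input
    size and inferred; every original point takes the label of its nearest
    resampled point within its block.  Output is written in the input's
    format with the predicted label column.
    """
    model, config = (checkpoint if isinstance(checkpoint, tuple)
                     else load_checkpoint(checkpoint))
    cloud = read_point_cloud(cloud_path, fmt)
    n_points = config.model.n_points
    bs = split_into_blocks(LabeledPointCloud(cloud.cloud, None),
                           target_points=n_points)
    rng = np.random.default_rng(seed)
    labels = np.empty(cloud.n, dtype=np.int64)
    for block, src in zip(bs.blocks, bs.source_indices):
        res = resample_block(block, n_points, rng)
        result, _ = _forward_block(model, res)
        pred = result.logits.labels
        nn = np.argmin(cdist(block.coords, res.coords), axis=1)
        labels[src] = pred[nn]
    out = LabeledPointCloud(cloud.cloud, labels)
    write_point_cloud(out, out_path, fmt)
    return out


def save_checkpoint(model: SegmentationModel, config: RunConfig, path):
    """Single-file checkpoint: all parameters + the embedded RunConfig."""
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(config.to_dict()),
             **{f"param/{k}": v for k, v in state.items()})


def load_checkpoint(path) -> tuple[SegmentationModel, RunConfig]:
    with np.load(path, allow_pickle=False) as z:
        config = RunConfig.from_dict(json.loads(str(z["__config__"])))
        state = {k[len("param/"):]: z[k] for k in z.files
                 if k.startswith("param/")}
    model = SegmentationModel(config.model)
    model.load_state_dict(state)
    return model, config
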