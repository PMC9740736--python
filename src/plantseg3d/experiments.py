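"""Desk-scale experiments: a reduced end-to-end benchmark and the ablation
harness.

The benchmark generates a seeded synthetic dataset of 30 plants (whole-plant
25/5 train/test split), trains a reduced network (d_m = 64, h = 4, 512-point
blocks, at most 30 epochs with early stopping) on one CPU, and reports
held-out per-class IoU / MIoU plus the mean absolute pairwise head cosine at
convergence.  The ablation harness re-runs the same seed with the network
components switched off one at a time:

* ``full``      — the complete model,
* ``no_rpc``    — relative position codes removed (absolute codes kept),
* ``no_sep``    — separation loss weight set to 0,
* ``baseline``  — both removed (plain two-branch attention backbone).

Problem sizes are deliberately small so the whole harness runs in minutes;
the interesting claims are directional (e.g. the separation loss lowers the
head cosine at convergence on the same seed), not absolute scores.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .cloud import BlockSet
from .network import ModelConfig
from .pipeline import RunConfig, TrainResult, evaluate, mean_abs_head_cosine, \
    train, _forward_block
from .errors import ValidationError
from .synthetic import DatasetResult, PlantSpec, generate_dataset

__all__ = ["scaled_run_config", "scaled_dataset", "eval_head_cosine",
           "run_scaled_benchmark", "run_ablation", "VARIANTS"]

VARIANTS = ("full", "no_rpc", "no_sep", "baseline")


def scaled_run_config(seed: int = 0) -> RunConfig:
    """The reduced-model configuration used by the desk-scale benchmark."""
    model = ModelConfig(
        n_points=512, d_m=64, h=4, d_k=16, d_v=16, ffn_hidden=64,
        m_fps=48, k_local=96, radii=(0.12, 0.25, 0.5), radius_local=0.25,
        k_max=12, rpc_hidden=24, c_r=24, c_a=12, highd_hidden=24,
        head_hidden=48, upsample="interp3", seed=seed)
    return RunConfig(model=model, learning_rate=2e-3, batch_size=4,
                     epochs=30, loss_scal=1.0, early_stop_patience=8,
                     seed=seed)


def scaled_dataset(seed: int = 0, n_plants: int = 30) -> DatasetResult:
    """30 default-spec synthetic plants, blocked and resampled at 512
    points, split 25/5 by whole plant."""
    return generate_dataset(n_plants, PlantSpec(), seed=seed,
                            target_points=512, n_points=512)


def apply_variant(config: RunConfig, variant: str) -> RunConfig:
    if variant not in VARIANTS:
        raise ValidationError(f"unknown ablation variant {variant!r}; "
                              f"expected one of {VARIANTS}")
    model = config.model
    if variant in ("no_rpc", "baseline"):
        model = replace(model, use_rpc=False)
    loss_scal = 0.0 if variant in ("no_sep", "baseline") else config.loss_scal
    return replace(config, model=model, loss_scal=loss_scal)


def eval_head_cosine(model, blocks: BlockSet) -> float:
    """Mean absolute pairwise head cosine over all attention modules,
    averaged over the given blocks."""
    vals = [mean_abs_head_cosine(_forward_block(model, b)[0]) for b in blocks]
    return float(np.mean(vals))


def run_scaled_benchmark(seed: int = 0, variant: str = "full",
                         dataset: DatasetResult | None = None,
                         log_fn=None) -> dict:
    """Train one variant on the seeded scaled dataset and evaluate held-out
    MIoU and head cosine.  Returns a flat result dict."""
    ds = dataset or scaled_dataset(seed)
    config = apply_variant(scaled_run_config(seed), variant)
    result: TrainResult = train(config, ds.train, ds.test, log_fn=log_fn)
    report = evaluate(result.model, ds.test)
    return {
        "variant": variant,
        "seed": seed,
        "n_train_blocks": len(ds.train),
        "n_test_blocks": len(ds.test),
        "epochs_run": len(result.history),
        "miou": report.miou,
        "iou": report.to_dict()["iou"],
        "head_cosine": eval_head_cosine(result.model, ds.test),
        "history": result.history,
        "model": result.model,
    }


def run_ablation(seed: int = 0, variants=("full", "no_sep"),
                 dataset: DatasetResult | None = None, log_fn=None) -> dict:
    """Run several variants on the identical dataset/seed and tabulate
    MIoU and head cosine per variant."""
    ds = dataset or scaled_dataset(seed)
    out = {}
    for v in variants:
        r = run_scaled_benchmark(seed, variant=v, dataset=ds, log_fn=log_fn)
        r.pop("model")
        out[v] = r
    return out
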