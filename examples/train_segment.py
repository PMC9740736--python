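"""Train the segmentation network on a small synthetic dataset.

Generates 8 plants (whole-plant train/test split), trains a reduced model
for a few epochs on one CPU, and prints the held-out per-organ IoU.  For
the full desk-scale benchmark (30 plants, up to 30 epochs, plus the
separation-loss ablation) see `plantseg3d ablate --seed 1` or
scripts/acceptance.py.
"""

from plantseg3d import evaluate, generate_dataset, train
from plantseg3d.experiments import scaled_run_config
from plantseg3d.synthetic import PlantSpec

ds = generate_dataset(8, PlantSpec(), seed=3, target_points=512, n_points=512)
print(f"{len(ds.train)} training blocks, {len(ds.test)} held-out blocks")

config = scaled_run_config(seed=3)
config.epochs = 8


def show(entry):
    print(f"  epoch {entry['epoch']}  total {entry['total']:.3f}  "
          f"ce {entry['cross_entropy']:.3f}  sep {entry['separation']:.3f}  "
          f"val MIoU {entry['val_miou']:.3f}")


result = train(config, ds.train, ds.test, log_fn=show)
report = evaluate(result.model, ds.test)
print("\nheld-out metrics:")
for organ, iou in report.to_dict()["iou"].items():
    print(f"  IoU {organ:7s} {iou:.3f}")
print(f"  MIoU       {report.miou:.3f}")
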