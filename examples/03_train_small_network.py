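"""Train a small fuzzy U-shape network on synthetic phantoms (a few minutes on CPU).

Run:  python examples/03_train_small_network.py
"""

import numpy as np

from fuzzyseg import NetworkConfig, PhantomParams, make_dataset
from fuzzyseg.train import RunConfig, evaluate_model, train_network

samples, folds = make_dataset(64, PhantomParams(size=64), seed=7, k_folds=8)
val_idx = folds[0]
fit_idx = np.setdiff1d(np.arange(len(samples)), val_idx)

cfg = RunConfig(
    network=NetworkConfig(encoder_family="small", input_size=(64, 64),
                          num_classes=5, base_channels=8, seed=7,
                          fuzzy_placement=((True, True),) * 5),
    optimizer="adam", learning_rate=3e-3, batch_size=8, epochs=15,
    lambda_s=1e-4, lambda_ch=1e-4, augment_ops=(), seed=7)

result = train_network(cfg, [samples[i] for i in fit_idx], [samples[i] for i in val_idx],
                       checkpoint_path="scratch/example_run/best.ckpt",
                       log_path="scratch/example_run/loss_log.csv")
print(result.history[["epoch", "Lc", "Ls", "LCh", "L", "val_mIoU"]].round(4).to_string(index=False))

report = evaluate_model(result.model, [samples[i] for i in val_idx])
print("\nvalidation mIoU:", round(report.miou, 4))
print("per-class IoU:", {k: round(v, 3) for k, v in report.summary()["per_class_IoU"].items()})
# Lc is the mean cross-entropy; Ls/LCh are the summed pixel/channel fuzzy
# entropies (down-weighted by 1e-4 here so they do not drown the class loss).
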