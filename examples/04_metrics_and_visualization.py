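"""Area metrics on a toy prediction and an uncertainty-heatmap figure.

Run after 03_train_small_network.py:  python examples/04_metrics_and_visualization.py
"""

import numpy as np

from fuzzyseg import binary_area_metrics, generate_phantom, PhantomParams
from fuzzyseg.metrics import MulticlassIoU
from fuzzyseg.networks import load_checkpoint
from fuzzyseg.visualize import visualize_uncertainty

# Binary tumor metrics on a deliberately imperfect prediction.
gt = np.zeros((16, 16), bool)
gt[4:10, 4:10] = True                  # 36 tumor pixels
pred = np.zeros((16, 16), bool)
pred[6:12, 6:12] = True                # shifted by 2
m = binary_area_metrics(pred, gt)
print("TPR %.3f  FPR %.3f  JI %.3f  DSC %.3f  AER %.3f" % (m.tpr, m.fpr, m.ji, m.dsc, m.aer))
print("identities: DSC = 2JI/(1+JI) =", round(2 * m.ji / (1 + m.ji), 3),
      " AER = FPR + (1-TPR) =", round(m.fpr + 1 - m.tpr, 3))

acc = MulticlassIoU(2).update(pred.astype(int), gt.astype(int))
print("binary IoU (class 1) equals JI:", round(acc.per_class_iou()[1], 3))

try:
    model = load_checkpoint("scratch/example_run/best.ckpt")
except (FileNotFoundError, ValueError):
    print("\nno checkpoint found - run examples/03_train_small_network.py first")
else:
    sample = generate_phantom(PhantomParams(size=64), seed=99)
    path = visualize_uncertainty(model, sample.image,
                                 "scratch/example_run/uncertainty.png", channels=(0, 1))
    print("\nwrote", path, "- input, per-block SFB uncertainty heatmaps "
          "(red = ambiguous), post-CFB channel maps, predicted mask")
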