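"""Uncertainty-map and channel-map visualization.

For each image the figure shows: the input, one per-block spatial
uncertainty heatmap (red = high, blue = low) per enabled spatial fuzzy
block at that block's native resolution, selected channels of the feature
map after the last channel fuzzy block, and the predicted mask rendered in
the class palette. Heatmap values are the raw uncertainty maps returned by
the forward pass; only the display is color-mapped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .autodiff import Tensor
from .metrics import CLASS_PALETTE
from .networks import FuzzyUNet
from .phantom import normalize_intensity

logger = logging.getLogger(__name__)

__all__ = ["mask_to_rgb", "visualize_uncertainty"]


def mask_to_rgb(mask: np.ndarray) -> np.ndarray:
    palette = np.asarray(CLASS_PALETTE, dtype=np.uint8)
    return palette[mask]


def visualize_uncertainty(model: FuzzyUNet, image: np.ndarray, out_path,
                          channels: tuple[int, ...] = (0, 1)) -> Path:
    """Render the diagnostic figure for one 8-bit image; returns the file path."""
    model.eval()
    norm = normalize_intensity(image).astype(np.float32)
    out = model(Tensor(norm[None, None]))
    pred = out.logits.data.argmax(axis=1)[0]
    u_maps = [u.data[0] for u in out.spatial_uncertainties]

    # Channel maps: rerun the encoder to grab the feature after the last CFB.
    channel_panels = []
    enabled = [i for i, (_, cfb) in enumerate(model.fuzzy) if cfb is not None]
    if enabled:
        feats, _ = model.encoder(Tensor(norm[None, None]), model.fuzzy)
        feat = feats[enabled[-1]].data[0]
        for c in channels:
            if 0 <= c < feat.shape[0]:
                channel_panels.append((c, feat[c]))
            else:
                logger.warning("channel %d out of range (feature has %d channels)", c, feat.shape[0])

    n_panels = 2 + len(u_maps) + len(channel_panels)
    fig, axes = plt.subplots(1, n_panels, figsize=(3 * n_panels, 3.2))
    axes = np.atleast_1d(axes)
    axes[0].imshow(image, cmap="gray", vmin=0, vmax=255)
    axes[0].set_title("input")
    k = 1
    for i, u in enumerate(u_maps):
        im = axes[k].imshow(u, cmap="jet", vmin=0, vmax=1)
        axes[k].set_title(f"SFB u (block {i + 1})")
        fig.colorbar(im, ax=axes[k], fraction=0.046)
        k += 1
    for c, fm in channel_panels:
        lo, hi = fm.min(), fm.max()
        logger.info("channel %d display-normalized from [%.3f, %.3f]", c, lo, hi)
        axes[k].imshow(fm, cmap="jet")
        axes[k].set_title(f"CFB channel {c}")
        k += 1
    axes[k].imshow(mask_to_rgb(pred))
    axes[k].set_title("prediction")
    for ax in axes:
        ax.axis("off")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
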