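"""Composite training loss: cross-entropy plus spatial/channel fuzzy entropies.

``L = Lc + lambda_s * Ls + lambda_ch * LCh`` where ``Lc`` is the mean
per-pixel cross-entropy, ``Ls`` sums the spatial uncertainty maps of every
enabled spatial fuzzy block and ``LCh`` sums the channel uncertainty vectors
of every enabled channel fuzzy block. The uncertainty terms are literal sums
per sample (averaged over the batch); with both weights at their default of
1 the total is the plain three-term sum. Because a pixel sum grows with
resolution while ``Lc`` is a mean, the weights are exposed so the scales can
be rebalanced; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, log_softmax
from .networks import SegmentationOutput

__all__ = ["LossBreakdown", "cross_entropy_loss", "spatial_entropy_loss",
           "channel_entropy_loss", "total_loss"]


@dataclass
class LossBreakdown:
    """All loss components as live autodiff tensors; floats via properties."""

    total: Tensor
    cross_entropy: Tensor
    spatial_entropy: Tensor
    channel_entropy: Tensor
    lambda_s: float = 1.0
    lambda_ch: float = 1.0

    @property
    def total_value(self) -> float:
        return float(self.total.data)

    @property
    def components(self) -> dict[str, float]:
        return {
            "Lc": float(self.cross_entropy.data),
            "Ls": float(self.spatial_entropy.data),
            "LCh": float(self.channel_entropy.data),
            "L": float(self.total.data),
        }


def cross_entropy_loss(logits, labels) -> Tensor:
    """Mean over batch and pixels of ``-log p_true`` under the soft-max.

    ``logits`` is ``(N, C, H, W)`` (or ``(C, H, W)``); ``labels`` integer
    ``(N, H, W)`` / ``(H, W)`` with values in ``{0..C-1}``.
    """
    logits = as_tensor(logits)
    if logits.ndim == 3:
        logits = logits.reshape(1, *logits.shape)
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[None]
    n, c, h, w = logits.shape
    if labels.shape != (n, h, w):
        raise ValueError(f"labels shape {labels.shape} does not match logits {(n, h, w)}")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels must lie in [0, {c - 1}]")
    logp = log_softmax(logits, axis=1)
    onehot = np.zeros((n, c, h, w), dtype=logits.dtype)
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
    return -(logp * Tensor(onehot)).sum() / float(n * h * w)


def _entropy_sum(values: list, per_sample_axes) -> Tensor:
    """Sum each tensor over its non-batch axes, then mean over the batch."""
    total = Tensor(np.zeros(()))
    for v in values:
        v = as_tensor(v)
        batch = v.shape[0]
        total = total + v.sum() / float(batch)
    return total


def spatial_entropy_loss(u_maps: list) -> Tensor:
    """Sum of pixel uncertainties over all spatial blocks (batch-averaged).

    Each entry is a ``(N, H, W)`` (or ``(H, W)``) uncertainty map; an empty
    list yields 0.
    """
    maps = [as_tensor(u) if as_tensor(u).ndim == 3 else as_tensor(u).reshape(1, *as_tensor(u).shape)
            for u in u_maps]
    return _entropy_sum(maps, None)


def channel_entropy_loss(h_vectors: list) -> Tensor:
    """Sum of channel uncertainties over all channel blocks (batch-averaged)."""
    vecs = [as_tensor(h) if as_tensor(h).ndim == 2 else as_tensor(h).reshape(1, -1)
            for h in h_vectors]
    return _entropy_sum(vecs, None)


def total_loss(output: SegmentationOutput, labels, lambda_s: float = 1.0,
               lambda_ch: float = 1.0) -> LossBreakdown:
    """Full training loss with its decomposition."""
    lc = cross_entropy_loss(output.logits, labels)
    ls = spatial_entropy_loss(output.spatial_uncertainties)
    lch = channel_entropy_loss(output.channel_uncertainties)
    total = lc + ls * lambda_s + lch * lambda_ch
    return LossBreakdown(total, lc, ls, lch, lambda_s, lambda_ch)
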