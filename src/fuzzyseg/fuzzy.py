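"""Spatial- and channel-wise fuzzy uncertainty-reduction blocks.

Both blocks share the same three-stage structure:

1. **Fuzzification** — a trainable membership head (1x1 convolution, sigmoid,
   1x1 convolution, soft-max) maps each pixel (spatial block) or each channel
   (channel block) of a feature map to a membership vector over the ``C``
   segmentation categories.
2. **Uncertainty representation** — the normalized fuzzy entropy

   .. math:: H(\\mu) = -\\frac{1}{\\log C} \\sum_{r=1}^{C} \\mu_r \\log \\mu_r

   turns each membership vector into an uncertainty degree in ``[0, 1]``:
   1 at the uniform vector (maximally ambiguous), 0 at one-hot vectors.
3. **Uncertainty reduction** — the refined map blends a freshly convolved
   "novel" feature with the input, weighting the novel feature by the
   uncertainty ``w`` and the original by ``1 - w``:
   ``X' = Conv3x3(X) * w + X * (1 - w)``.

Feature maps are channels-first ``(N, Ch, H, W)``. The channel block's
membership head operates on the flattened spatial content, so its parameter
count is tied to the spatial resolution it was constructed for; calling it at
another resolution is a hard error rather than silent pooling.
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy

from .autodiff import Tensor, as_tensor, softmax
from . import nn

EPS = 1e-12

__all__ = [
    "fuzzy_entropy",
    "spatial_uncertainty",
    "channel_uncertainty",
    "spatial_reduce",
    "channel_reduce",
    "MembershipHead",
    "SpatialFuzzyBlock",
    "ChannelFuzzyBlock",
]


# ---------------------------------------------------------------- functional
def fuzzy_entropy(memberships, axis: int = -1):
    """Normalized fuzzy entropy of membership vectors along ``axis``.

    Accepts a plain numpy array (returns an array/scalar, computed in
    float64) or a :class:`Tensor` (stays on the autodiff tape). Inputs must
    be valid membership vectors: entries in ``[0, 1]`` summing to 1 along
    ``axis``. ``0 * log 0`` is taken as 0; the ``1 / log C`` normalization
    makes the result independent of the logarithm base.
    """
    if isinstance(memberships, Tensor):
        c = memberships.shape[axis]
        if c < 2:
            raise ValueError("fuzzy entropy needs at least 2 categories")
        mu = memberships.clamp(EPS, 1.0)
        return ((mu * mu.log()).sum(axis=axis) / (-np.log(c))).clamp(0.0, 1.0)

    mu = np.asarray(memberships, dtype=np.float64)
    c = mu.shape[axis]
    if c < 2:
        raise ValueError("fuzzy entropy needs at least 2 categories")
    if np.any(mu < -1e-9):
        raise ValueError("memberships must be nonnegative")
    sums = mu.sum(axis=axis)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("memberships must sum to 1 along the category axis")
    h = -xlogy(mu, mu).sum(axis=axis) / np.log(c)   # xlogy gives 0*log0 = 0 exactly
    return np.clip(h, 0.0, 1.0) + 0.0               # +0.0 normalizes -0.0


def spatial_uncertainty(mu):
    """Per-pixel fuzzy entropy of a spatial membership map.

    ``mu`` has the category axis at position 1 for batched ``(N, C, H, W)``
    input (Tensor or array) or last for a single ``(H, W, C)`` array.
    """
    if isinstance(mu, Tensor) or (isinstance(mu, np.ndarray) and mu.ndim == 4):
        return fuzzy_entropy(mu, axis=1)
    return fuzzy_entropy(mu, axis=-1)


def channel_uncertainty(pi):
    """Per-channel fuzzy entropy of a ``(Ch, C)`` (or batched) membership map."""
    return fuzzy_entropy(pi, axis=-1)


def _blend(x: Tensor, novel: Tensor, weight: Tensor) -> Tensor:
    return novel * weight + x * (1.0 - weight)


def spatial_reduce(x, u, conv: "nn.Conv2d") -> Tensor:
    """Blend ``Conv3x3(X)`` and ``X`` with the per-pixel uncertainty map ``u``.

    ``u`` (shape ``(N, H, W)`` or ``(H, W)``) broadcasts identically over all
    channels.
    """
    x = as_tensor(x)
    u = as_tensor(u)
    if u.ndim == 2:
        u = u.reshape(1, 1, *u.shape)
    elif u.ndim == 3:
        u = u.reshape(u.shape[0], 1, *u.shape[1:])
    if u.shape[-2:] != x.shape[-2:]:
        raise ValueError(f"spatial shape mismatch: features {x.shape[-2:]}, uncertainty {u.shape[-2:]}")
    return _blend(x, conv(x), u)


def channel_reduce(x, h, conv: "nn.Conv2d") -> Tensor:
    """Blend ``Conv3x3(X)`` and ``X`` with per-channel scalar weights ``h``."""
    x = as_tensor(x)
    h = as_tensor(h)
    if h.ndim == 1:
        h = h.reshape(1, -1, 1, 1)
    elif h.ndim == 2:
        h = h.reshape(h.shape[0], h.shape[1], 1, 1)
    if h.shape[1] != x.shape[1]:
        raise ValueError(f"channel count mismatch: features have {x.shape[1]}, weights {h.shape[1]}")
    return _blend(x, conv(x), h)


# ------------------------------------------------------------------- modules
class MembershipHead(nn.Module):
    """Trainable membership function: 1x1 conv -> sigmoid -> 1x1 conv -> soft-max.

    Both 1x1 layers have ``num_classes`` kernels, so the hidden width equals
    the category count.
    """

    def __init__(self, in_channels: int, num_classes: int, rng: np.random.Generator):
        super().__init__()
        if num_classes < 2:
            raise ValueError("membership head needs at least 2 categories")
        self.in_channels = in_channels
        self.num_classes = num_classes
        self.conv1 = nn.Conv2d(in_channels, num_classes, 1, rng=rng)
        self.conv2 = nn.Conv2d(num_classes, num_classes, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return softmax(self.conv2(self.conv1(x).sigmoid()), axis=1)


class SpatialFuzzyBlock(nn.Module):
    """Per-pixel fuzzy uncertainty estimation and reduction.

    ``forward`` returns the refined feature map and the uncertainty map
    ``(N, H, W)``; the latter feeds the spatial-entropy loss term and
    visualization.
    """

    def __init__(self, channels: int, num_classes: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.num_classes = num_classes
        self.membership = MembershipHead(channels, num_classes, rng)
        self.reduce_conv = nn.Conv2d(channels, channels, 3, stride=1, padding=1, rng=rng)

    def forward(self, x) -> tuple[Tensor, Tensor]:
        x = as_tensor(x)
        if x.shape[1] != self.channels:
            raise ValueError(f"block built for {self.channels} channels, got {x.shape[1]}")
        mu = self.membership(x)
        u = spatial_uncertainty(mu)
        return spatial_reduce(x, u, self.reduce_conv), u


class ChannelFuzzyBlock(nn.Module):
    """Per-channel fuzzy uncertainty estimation and reduction.

    The feature map ``(N, Ch, H, W)`` is reshaped to a ``1 x Ch`` grid whose
    ``H*W`` "channels" are the flattened spatial content, so the membership
    head's 1x1 convolutions act per channel of the original map. Because the
    head takes ``H*W`` input channels, the block is bound to the spatial size
    given at construction.
    """

    def __init__(self, channels: int, num_classes: int, spatial_size: tuple[int, int],
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.num_classes = num_classes
        self.spatial_size = tuple(spatial_size)
        hw = self.spatial_size[0] * self.spatial_size[1]
        self.membership = MembershipHead(hw, num_classes, rng)
        self.reduce_conv = nn.Conv2d(channels, channels, 3, stride=1, padding=1, rng=rng)

    def memberships(self, x: Tensor) -> Tensor:
        """Channel membership map ``(N, Ch, C)``."""
        n, ch, hgt, wid = x.shape
        if (hgt, wid) != self.spatial_size:
            raise ValueError(
                f"channel fuzzy block was built for spatial size {self.spatial_size} "
                f"(its membership head takes H*W input channels) but got {(hgt, wid)}; "
                "construct the network for the resolution you intend to run")
        # (N, Ch, H, W) -> (N, HW, 1, Ch): channels become the spatial axis.
        v = x.reshape(n, ch, hgt * wid).transpose(0, 2, 1).reshape(n, hgt * wid, 1, ch)
        pi = self.membership(v)                       # (N, C, 1, Ch)
        return pi.reshape(n, self.num_classes, ch).transpose(0, 2, 1)

    def forward(self, x) -> tuple[Tensor, Tensor]:
        x = as_tensor(x)
        if x.shape[1] != self.channels:
            raise ValueError(f"block built for {self.channels} channels, got {x.shape[1]}")
        pi = self.memberships(x)
        h = channel_uncertainty(pi)                   # (N, Ch)
        return channel_reduce(x, h, self.reduce_conv), h
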