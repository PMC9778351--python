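"""Fuzzy entropy and the two uncertainty-reduction blocks on a toy feature map.

Run:  python examples/01_fuzzy_entropy_blocks.py
"""

import numpy as np

from fuzzyseg import SpatialFuzzyBlock, Tensor, fuzzy_entropy
from fuzzyseg.fuzzy import ChannelFuzzyBlock

# Normalized fuzzy entropy: 1 = maximally ambiguous, 0 = certain.
print("H(uniform, C=5)  =", fuzzy_entropy(np.full(5, 0.2)))
print("H(one-hot)       =", fuzzy_entropy(np.array([1.0, 0, 0, 0, 0])))
print("H([.5,.25,.25])  =", round(float(fuzzy_entropy(np.array([0.5, 0.25, 0.25]))), 4))

# A random 6-channel feature map on a 5x5 grid (batch of 2).
rng = np.random.default_rng(0)
x = Tensor(rng.normal(size=(2, 6, 5, 5)).astype(np.float32))

sfb = SpatialFuzzyBlock(channels=6, num_classes=5, rng=rng)
refined, u = sfb(x)
print("\nspatial block: refined", refined.shape, "uncertainty map", u.shape)
print("mean pixel uncertainty u =", round(float(u.data.mean()), 4),
      " (near 1 at random init: memberships are still ambiguous)")

cfb = ChannelFuzzyBlock(channels=6, num_classes=5, spatial_size=(5, 5), rng=rng)
refined_c, h = cfb(x)
print("channel block: refined", refined_c.shape, "uncertainty vector", h.shape)
print("per-channel uncertainty h[0] =", np.round(h.data[0], 4))
# Each output blends a fresh 3x3 convolution (weight u or h) with the input
# (weight 1-u / 1-h): ambiguous pixels/channels get replaced, certain ones kept.
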