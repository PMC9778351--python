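"""Generate a small synthetic breast-phantom dataset and inspect it.

Run:  python examples/02_generate_phantoms.py
"""

import numpy as np

from fuzzyseg import PhantomParams, make_dataset, normalize_intensity
from fuzzyseg.metrics import CLASS_NAMES
from fuzzyseg.phantom import write_dataset

params = PhantomParams(size=64, tumor_prob=0.9, seed=0)
samples, folds = make_dataset(16, params, seed=0, k_folds=4)

s = samples[0]
print("image:", s.image.shape, s.image.dtype, " mask classes:", np.unique(s.mask))
for c, name in enumerate(CLASS_NAMES):
    print(f"  {name:10s} {100 * (s.mask == c).mean():5.1f}% of pixels")
print("normalized intensity range:",
      normalize_intensity(s.image).min(), "..", normalize_intensity(s.image).max())
print("folds:", [len(f) for f in folds], "(disjoint, exhaustive)")

manifest = write_dataset(samples, folds, "scratch/example_dataset", params)
print("wrote", len(manifest), "image/mask PNG pairs to scratch/example_dataset")
# Images carry speckle, blurred band boundaries and dark background decoys;
# masks are indexed PNGs in the black/green/yellow/blue/red class palette.
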