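# Methods

## Problem and model

Breast-ultrasound (BUS) B-mode images are low-contrast, speckled, and contain
regions whose intensity is genuinely ambiguous: tumor tissue resembles dark
background patches, and the fat/mammary/muscle band boundaries are blurred.
`fuzzyseg` implements a U-shape semantic-segmentation network whose encoder
features are repeatedly *de-fuzzified*: after each encoder block, a
spatial-wise fuzzy block (SFB) and then a channel-wise fuzzy block (CFB)
estimate how ambiguous each pixel (respectively channel) of the feature map
is and replace the ambiguous parts with freshly convolved features.

Both blocks share three stages.

**Fuzzification.** A trainable membership head maps the feature map
`X ∈ R^{H×W×Ch}` to per-category membership vectors: a 1×1 convolution to the
`C` category channels, a sigmoid, a second 1×1 convolution (both layers have
`C` kernels, so the hidden width equals the category count), and a soft-max
over categories. The SFB applies this per pixel (`μ ∈ R^{H×W×C}`); the CFB
first flattens the spatial content so each channel becomes one `H·W`-vector
and applies the same head per channel (`π ∈ R^{Ch×C}`).

**Uncertainty representation.** Each membership vector is scored by the
normalized fuzzy entropy

    H(μ) = −(1/log C) · Σ_r μ_r log μ_r,   0·log 0 := 0,

which is 1 exactly at the uniform vector (the pixel/channel could be any
category), 0 exactly at one-hot vectors, and independent of the logarithm
base because of the `1/log C` factor. This yields a per-pixel uncertainty map
`u ∈ [0,1]^{H×W}` (SFB) or a per-channel uncertainty vector
`h ∈ [0,1]^{Ch}` (CFB).

**Uncertainty reduction.** A 3×3 convolution with `Ch` kernels (stride 1,
padding 1, no nonlinearity) produces a novel feature, blended with the input
using the uncertainty as the weight of the novel part:

    X' = Conv3×3(X) ⊗ u ⊕ X ⊗ (1 − u)        (SFB; u broadcast over channels)
    X_Ch = Conv3×3(X) ⊙ h ⊕ X ⊙ (1 − h)      (CFB; h_j scales channel j)

With `u ≡ 0` the block is the identity; with `u ≡ 1` it returns the pure
convolution. These identities, and equivalence of the full blocks with
scalar-loop reimplementations, are pinned by tests.

## Network

The encoder has five blocks (families: VGG-16-style stacks, ResNet-101-style
bottleneck stages with canonical depths 3/4/23/3, or a lightweight `small`
family — two 3×3 conv+ReLU per block — for CPU-scale work), halving
resolution four times, so the input size must be divisible by 16. The
ResNet stem uses stride 1 rather than the canonical stride-2 stem so that
five blocks give exactly four halvings like the other families. Fuzzy-block
placement is configurable per block (`(use_SFB, use_CFB)` × 5); the refined
features feed both the next encoder block and the skip connection, so the
decoder also benefits from uncertainty reduction. With all placements off
the model is exactly the plain U-shape baseline.

The decoder is a standard U-Net-style mirror: the first stage refines the
bottleneck at its own resolution (the five-block encoder only downsamples
four times, so one of the five decoder stages cannot upsample), the next
four each apply a learned 2×2 transposed convolution, concatenate the
matching skip, and run two 3×3 conv+ReLU; a final 1×1 convolution produces
`C` logits. Soft-max + arg-max (ties to the lowest class index) gives the
predicted mask.

Because the CFB's membership head takes `H·W` input channels, each CFB is
bound to the spatial resolution it was constructed for; a forward pass at a
different size raises an error rather than silently pooling.

## Loss

`L = Lc + λs·Ls + λch·LCh` where `Lc` is the mean per-pixel cross-entropy,
`Ls = Σ_l Σ_i u_i^l` sums every SFB's uncertainty map and `LCh = Σ_l Σ_j h_j^l`
sums every CFB's uncertainty vector (literal sums per sample, averaged over
the batch). Minimizing `L` trains the segmentation and pushes the network
toward self-certain features simultaneously. Defaults are `λs = λch = 1`
(the plain three-term sum). Note the scale mismatch: at 64×64 with five SFBs
the pixel sum is O(10³–10⁴) while `Lc` is O(1), so the uncertainty terms
dominate gradients unless down-weighted; the package's desk-scale recipe
uses `λs = λch = 1e-4`, which brings the terms to comparable magnitude.
Probabilities are clamped at 1e-12 inside logarithms.

A property test verifies that one small gradient step on the uncertainty
terms alone strictly decreases the mean uncertainty of a fixed batch.

## Compute core

No GPU framework is used: the package ships a small numpy reverse-mode
autodiff engine (`fuzzyseg.autodiff`) with im2col convolution, transposed
convolution (kernel = stride), max-pooling, batch-norm and the pointwise
ops the model needs, verified against central finite differences. Parameters
are float32, initialized with fan-in-scaled (He) Gaussian noise from an
explicit seeded generator; no pretraining. Optimizers: SGD with classical
momentum, and Adam. Checkpoints are zip archives holding the parameter
arrays plus the embedded network config, restoring bit-exactly.

## Metrics

Binary area metrics (tumor vs rest): TPR, FPR, JI (Jaccard), DSC (Dice),
AER, all normalized as set ratios against the ground-truth area, so FPR and
AER can exceed 1. The identities `DSC = 2·JI/(1+JI)` and
`AER = FPR + (1 − TPR)` hold by algebra and are enforced numerically.
Binary metrics are computed per image and averaged over the split; images
with an empty tumor ground truth are excluded from that average (the
denominator is the tumor area) and counted. Multi-class IoU accumulates
intersection/union counts over the whole split before dividing
(dataset-level convention, stable for images missing a class); mIoU is the
unweighted mean over classes including background; a class absent from both
prediction and ground truth is flagged undefined and excluded with a
warning. Fold aggregation is the unweighted mean of every metric.

## Synthetic phantoms

The generator emulates the gross structure of a five-class BUS image:
fat/mammary/muscle bands whose boundaries undulate sinusoidally (defaults:
boundary fractions 0.22/0.55/0.80 of the height, amplitude 3%), an
elliptical tumor embedded strictly inside the mammary band (probability
0.9, semi-axis 8–16% of the image, placed with capped retries), dark
background patches matched to tumor intensity (the classic false-positive
bait), Gaussian boundary blur (σ = 1.5 px) and unit-mean multiplicative
gamma speckle (strength 0.15). Tissue mean intensities (8-bit):
background 45, fat 175, mammary 125, muscle 95, tumor 40 — chosen so fat is
brightest, the tumor is darker than its surrounding mammary band, and
decoys are tumor-like. With speckle and blur at 0 the image is piecewise
constant. Everything is deterministic given the seed.

What the phantoms do *not* model: acoustic physics (attenuation, shadowing,
refraction), probe geometry, patient variability, and real intensity
statistics. Passing tests on phantoms demonstrates that the architecture,
loss and training machinery work and that the network can exploit
intensity+position cues under speckle; they say nothing quantitative about
performance on clinical BUS data. Real datasets in the same folder layout
(grayscale PNGs plus palette or binary masks, mapped to classes {0, 4})
drop in via `read_pair`/`read_dataset`.

Preprocessing maps 8-bit intensities to `[−1, 1]` by `x/127.5 − 1`.
Augmentation (horizontal flip, horizontal/vertical shift, rotation, zoom,
shear) applies the same geometric transform to image (bilinear) and mask
(nearest neighbor — labels stay categorical); magnitudes are bounded
(shift ≤ 10%, rotation ≤ 15°, zoom 0.9–1.1, shear ≤ 10°) and exposed;
exposed pixels become background class/intensity.

## Training protocol and desk-scale recipe

`RunConfig` defaults mirror the reference protocol: SGD, learning rate
0.001, momentum 0.99, batch 12, 80 epochs, 128×128 input, λs = λch = 1,
10-fold cross-validation (each fold keeps 10% of its training split for
validation; the checkpoint with the best validation mIoU is kept — the
selection rule is logged). That protocol is sized for GPU-scale training;
for CPU-scale experiments the package uses a scaled recipe chosen a priori:
`small` encoder (base width 8), 64×64 phantoms, Adam 3e-3, batch 8,
15 epochs, λs = λch = 1e-4, no augmentation (the generator already varies
geometry). Under these conditions (64 phantoms, one fold held out) the
end-to-end test requires validation mIoU ≥ 0.70 and a trained tumor IoU
strictly above an untrained network's. The ablation machinery reproduces
three placement designs — cumulative (blocks 1..k), individual (block k
only), and the 4-row SFB/CFB on-off grid — at whatever scale the config
specifies.

## Numerical choices and edge cases

- Entropy inputs are validated (nonnegative, sum 1 within 1e-6); on the
  autodiff path memberships are clamped to [1e-12, 1] before the log and the
  result to [0, 1] (gradients pass inside the bounds).
- Arg-max ties break toward the lowest class index (numpy convention).
- `binary_area_metrics` raises on an empty ground-truth mask rather than
  returning NaNs.
- Mask PNGs are palette-indexed; unknown palette colors are an error listing
  the offending colors.
- Max-pool ties route the gradient to the first maximal element.
- Forward passes are reproducible bit-for-bit given a fixed seed and
  checkpoint on the same platform/BLAS.

## Known limitations

- The channel fuzzy block's parameter count scales with `H·W`, which is
  intrinsic to its flattened-spatial membership head; large inputs make the
  first-block CFB head big.
- The numpy engine is single-process and eager; it is sized for the small
  encoder family at ≤128×128. The VGG-16 and ResNet-101 families are built
  and verified structurally, but training them at full scale is outside the
  package's CPU envelope.
- Phantom realism is a stand-in, as discussed above.
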