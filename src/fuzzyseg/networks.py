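"""U-shape segmentation networks with optional fuzzy uncertainty-reduction blocks.

The encoder is one of three five-block families (``vgg16``, ``resnet101`` or a
lightweight ``small`` family for CPU-scale experiments); the decoder mirrors it
with learned x2 upsampling and skip concatenation. After any encoder block a
spatial fuzzy block and then a channel fuzzy block can be inserted; their
refined output feeds both the next encoder block and the skip connection, and
their uncertainty maps/vectors are surfaced for the loss and visualization.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from io import BytesIO
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor, concat, softmax
from .fuzzy import ChannelFuzzyBlock, SpatialFuzzyBlock

CHECKPOINT_VERSION = 1

__all__ = [
    "NetworkConfig",
    "SegmentationOutput",
    "build_encoder",
    "assemble_network",
    "FuzzyUNet",
    "predict_segmentation",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    """Architecture description; fully determines the parameter shapes.

    ``fuzzy_placement`` holds one ``(use_spatial, use_channel)`` pair per
    encoder block 1-5. ``base_channels`` scales the ``small`` family only.
    """

    encoder_family: str = "small"
    input_size: tuple[int, int] = (128, 128)
    num_classes: int = 5
    base_channels: int = 8
    fuzzy_placement: tuple[tuple[bool, bool], ...] = field(
        default_factory=lambda: tuple((True, True) for _ in range(5)))
    seed: int = 0

    def __post_init__(self):
        self.input_size = tuple(int(v) for v in self.input_size)
        self.fuzzy_placement = tuple((bool(a), bool(b)) for a, b in self.fuzzy_placement)
        if self.encoder_family not in ("vgg16", "resnet101", "small"):
            raise ValueError(f"unknown encoder family {self.encoder_family!r}")
        if len(self.fuzzy_placement) != 5:
            raise ValueError("fuzzy_placement must list exactly 5 (spatial, channel) pairs")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        for v in self.input_size:
            if v % 16:
                raise ValueError("input size must be divisible by 16 (four downsamplings)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        d["fuzzy_placement"] = [list(p) for p in self.fuzzy_placement]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["input_size"] = tuple(d["input_size"])
        d["fuzzy_placement"] = tuple(tuple(p) for p in d["fuzzy_placement"])
        return cls(**d)


@dataclass
class SegmentationOutput:
    """Forward-pass result: logits plus the per-block uncertainty outputs."""

    logits: Tensor                      # (N, C, H, W)
    spatial_uncertainties: list         # Tensors (N, H_l, W_l), one per enabled spatial block
    channel_uncertainties: list         # Tensors (N, Ch_l), one per enabled channel block

    def probabilities(self) -> np.ndarray:
        return softmax(self.logits, axis=1).data


# ------------------------------------------------------------------- encoders
class _ConvBlock(nn.Module):
    """n x (3x3 conv + ReLU)."""

    def __init__(self, in_ch: int, out_ch: int, n_convs: int, rng):
        super().__init__()
        layers = []
        for i in range(n_convs):
            layers += [nn.Conv2d(in_ch if i == 0 else out_ch, out_ch, 3, padding=1, rng=rng), nn.ReLU()]
        self.body = nn.Sequential(*layers)

    def forward(self, x):
        return self.body(x)


class _Bottleneck(nn.Module):
    """ResNet bottleneck unit (1x1 -> 3x3 -> 1x1, BN after each conv)."""

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, stride: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, stride=stride, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid_ch)
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.downsample = None
        if stride != 1 or in_ch != out_ch:
            self.downsample = nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)

    def forward(self, x):
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        skip = self.downsample(x) if self.downsample is not None else x
        return (y + skip).relu()


class _ResNetStage(nn.Module):
    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, depth: int, stride: int, rng):
        super().__init__()
        units = [_Bottleneck(in_ch, mid_ch, out_ch, stride, rng)]
        units += [_Bottleneck(out_ch, mid_ch, out_ch, 1, rng) for _ in range(depth - 1)]
        self.body = nn.Sequential(*units)

    def forward(self, x):
        return self.body(x)


class Encoder(nn.Module):
    """Five-block encoder exposing every block's output for skips.

    Block ``l`` runs at resolution ``input / 2^(l-1)``; a 2x2 max-pool sits
    between consecutive blocks for the ``vgg16``/``small`` families, while the
    ``resnet101`` family downsamples with strided bottlenecks (stage depths
    3/4/23/3, stride-1 stem so the five blocks give exactly four halvings).
    """

    FAMILIES = ("vgg16", "resnet101", "small")

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        fam = config.encoder_family
        self.family = fam
        self.pooled = fam != "resnet101"
        if fam == "small":
            b = config.base_channels
            chans = [b, 2 * b, 3 * b, 4 * b, 4 * b]
            self.blocks = [_ConvBlock(1 if i == 0 else chans[i - 1], chans[i], 2, rng)
                           for i in range(5)]
        elif fam == "vgg16":
            chans = [64, 128, 256, 512, 512]
            depths = [2, 2, 3, 3, 3]
            self.blocks = [_ConvBlock(1 if i == 0 else chans[i - 1], chans[i], depths[i], rng)
                           for i in range(5)]
        else:  # resnet101
            chans = [64, 256, 512, 1024, 2048]
            self.blocks = [nn.Sequential(nn.Conv2d(1, 64, 7, stride=1, padding=3, rng=rng),
                                         nn.BatchNorm2d(64), nn.ReLU())]
            mids = [64, 128, 256, 512]
            depths = [3, 4, 23, 3]
            for i in range(4):
                self.blocks.append(_ResNetStage(chans[i], mids[i], chans[i + 1],
                                                depths[i], stride=2, rng=rng))
        self.channels = chans
        for i, blk in enumerate(self.blocks):
            setattr(self, f"block{i + 1}", blk)
        self.pool = nn.MaxPool2d(2)

    def forward(self, x, fuzzy_blocks=None):
        """Return the five block outputs (post fuzzy blocks when given)."""
        feats = []
        uncertainties = ([], [])
        for i, blk in enumerate(self.blocks):
            if i > 0 and self.pooled:
                x = self.pool(x)
            x = blk(x)
            if fuzzy_blocks is not None:
                sfb, cfb = fuzzy_blocks[i]
                if sfb is not None:
                    x, u = sfb(x)
                    uncertainties[0].append(u)
                if cfb is not None:
                    x, h = cfb(x)
                    uncertainties[1].append(h)
            feats.append(x)
        return feats, uncertainties


def build_encoder(config: NetworkConfig, rng: np.random.Generator | None = None) -> Encoder:
    rng = rng or np.random.default_rng(config.seed)
    return Encoder(config, rng)


# -------------------------------------------------------------------- decoder
class _DecoderStage(nn.Module):
    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, upsample: bool, rng):
        super().__init__()
        self.upsample = upsample
        if upsample:
            self.up = nn.ConvTranspose2d(in_ch, out_ch, 2, rng=rng)
            merged = out_ch + skip_ch
        else:
            merged = in_ch
        self.refine = _ConvBlock(merged, out_ch, 2, rng)

    def forward(self, x, skip=None):
        if self.upsample:
            x = self.up(x)
            x = concat([x, skip], axis=1)
        return self.refine(x)


class FuzzyUNet(nn.Module):
    """U-shape segmentation network with configurable fuzzy-block placement."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = Encoder(config, rng)
        chans = self.encoder.channels
        h, w = config.input_size

        self.fuzzy = []
        for i, (use_s, use_c) in enumerate(config.fuzzy_placement):
            res = (h // 2 ** i, w // 2 ** i)
            sfb = SpatialFuzzyBlock(chans[i], config.num_classes, rng) if use_s else None
            cfb = ChannelFuzzyBlock(chans[i], config.num_classes, res, rng) if use_c else None
            if sfb is not None:
                setattr(self, f"sfb{i + 1}", sfb)
            if cfb is not None:
                setattr(self, f"cfb{i + 1}", cfb)
            self.fuzzy.append((sfb, cfb))

        # Five decoder stages: the first refines at the bottleneck resolution,
        # the remaining four each double resolution and merge a skip.
        self.dec1 = _DecoderStage(chans[4], 0, chans[4], upsample=False, rng=rng)
        self.dec2 = _DecoderStage(chans[4], chans[3], chans[3], upsample=True, rng=rng)
        self.dec3 = _DecoderStage(chans[3], chans[2], chans[2], upsample=True, rng=rng)
        self.dec4 = _DecoderStage(chans[2], chans[1], chans[1], upsample=True, rng=rng)
        self.dec5 = _DecoderStage(chans[1], chans[0], chans[0], upsample=True, rng=rng)
        self.head = nn.Conv2d(chans[0], config.num_classes, 1, rng=rng)

    def forward(self, x) -> SegmentationOutput:
        x = as_tensor(x)
        if x.ndim == 3:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        feats, (u_maps, h_vecs) = self.encoder(x, self.fuzzy)
        y = self.dec1(feats[4])
        y = self.dec2(y, feats[3])
        y = self.dec3(y, feats[2])
        y = self.dec4(y, feats[1])
        y = self.dec5(y, feats[0])
        return SegmentationOutput(self.head(y), u_maps, h_vecs)


def assemble_network(config: NetworkConfig) -> FuzzyUNet:
    """Build the full network described by ``config``."""
    return FuzzyUNet(config)


def predict_segmentation(model: FuzzyUNet, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Segment one normalized image; returns ``(label mask, class probabilities)``.

    ``image`` is ``(H, W)`` with intensities in ``[-1, 1]`` at the configured
    input size — resizing is the caller's job. Ties in the arg-max break
    toward the lowest class index.
    """
    h, w = model.config.input_size
    image = np.asarray(image, dtype=np.float32)
    if image.shape != (h, w):
        raise ValueError(f"expected image of shape {(h, w)}, got {image.shape}")
    if image.min() < -1.0 - 1e-6 or image.max() > 1.0 + 1e-6:
        raise ValueError("image intensities must be normalized to [-1, 1]")
    model.eval()
    out = model(Tensor(image[None, None]))
    probs = out.probabilities()[0]           # (C, H, W)
    return probs.argmax(axis=0).astype(np.int64), probs


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(model: FuzzyUNet, path) -> None:
    """Archive all parameters plus the embedded config (self-describing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = BytesIO()
    np.savez(buf, **model.state_dict())
    meta = {"format_version": CHECKPOINT_VERSION, "config": model.config.to_dict()}
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path, num_classes: int | None = None) -> FuzzyUNet:
    """Rebuild a model from a checkpoint; parameters restore bit-exactly."""
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            with np.load(BytesIO(zf.read("params.npz"))) as npz:
                state = {k: npz[k] for k in npz.files}
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupt or unrecognized checkpoint: {path}") from exc
    if meta.get("format_version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta.get('format_version')}")
    config = NetworkConfig.from_dict(meta["config"])
    if num_classes is not None and num_classes != config.num_classes:
        raise ValueError(f"checkpoint has {config.num_classes} classes, requested {num_classes}")
    model = FuzzyUNet(config)
    model.load_state_dict(state)
    return model
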