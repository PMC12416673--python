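"""The segmentation network: harmonic-dense encoder, receptive-field-block
skips, and a partial decoder with multiplicative dense aggregation.

Harmonic connectivity: inside a block, layer k takes shortcuts only from
layers k − 2ⁿ for every power of two dividing k (layer 0 being the block
input), instead of DenseNet's all-to-all links; layers sitting at higher
powers of two are widened geometrically (growth_rate · multiplier^p, rounded
down to even) to compensate.  The block output concatenates the last layer
and all odd-indexed layers, whose activations are the only ones that must be
kept to the end.

The encoder is a two-conv stride-2 stem followed by four stages
(block → 1×1 transition → 2× downsample) producing features at 1/4 … 1/32
of the input.  Following the cascaded-partial-decoder argument, the shallow
1/4 features are discarded: the three deepest scales pass through RFB
modules (multi-branch dilated convolutions enlarging the receptive field)
and are fused by the aggregation decoder — coarser maps bilinearly upsampled
and combined with finer ones by element-wise multiplication, the fused
streams concatenated, refined by convolution, added to a skip projection,
and projected to single-channel logits at 1/8 scale, then upsampled to full
resolution.

Four ablation variants are exposed: ``baseline`` (plain double-conv stages,
linear skips), ``hard`` (harmonic blocks only), ``rfb`` (RFB skips only) and
``full``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "HardBlockSpec",
    "ModelConfig",
    "hard_block_links",
    "hard_block_channels",
    "HardBlock",
    "RFB",
    "Aggregator",
    "VesselSegmenter",
    "build_model",
    "count_parameters",
]

VARIANTS = ("baseline", "hard", "rfb", "full")


# ---------------------------------------------------------------------------
# harmonic connectivity rule
# ---------------------------------------------------------------------------

def hard_block_links(k: int) -> set[int]:
    """Input layers of layer ``k``: {k − 2ⁿ : 2ⁿ divides k}."""
    if k < 1:
        raise ValueError(f"layer index must be >= 1, got {k}")
    links = set()
    step = 1
    while k % step == 0:
        links.add(k - step)
        step *= 2
    return links


def hard_block_channels(k: int, growth_rate: int,
                        growth_multiplier: float) -> int:
    """Width of layer ``k``: growth·multiplier^p floored to even, p = v₂(k)."""
    if k < 1:
        raise ValueError(f"layer index must be >= 1, got {k}")
    p = 0
    while k % (2 ** (p + 1)) == 0:
        p += 1
    raw = growth_rate * growth_multiplier**p
    return 2 * int(raw // 2)


@dataclass
class HardBlockSpec:
    n_layers: int
    growth_rate: int
    growth_multiplier: float
    in_channels: int
    links: list[set[int]] = field(default_factory=list)
    layer_channels: list[int] = field(default_factory=list)
    out_layers: list[int] = field(default_factory=list)
    out_channels: int = 0

    @classmethod
    def from_rule(cls, n_layers: int, growth_rate: int,
                  growth_multiplier: float, in_channels: int
                  ) -> "HardBlockSpec":
        if n_layers < 1:
            raise ValueError("a block needs at least one layer")
        links = [set()]  # layer 0 = block input
        channels = [in_channels]
        for k in range(1, n_layers + 1):
            links.append(hard_block_links(k))
            channels.append(
                hard_block_channels(k, growth_rate, growth_multiplier))
        out_layers = sorted({n_layers} | {k for k in range(1, n_layers + 1)
                                          if k % 2 == 1})
        out_channels = sum(channels[k] for k in out_layers)
        return cls(n_layers=n_layers, growth_rate=growth_rate,
                   growth_multiplier=growth_multiplier,
                   in_channels=in_channels, links=links,
                   layer_channels=channels, out_layers=out_layers,
                   out_channels=out_channels)


class HardBlock(nn.Module):
    def __init__(self, spec: HardBlockSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        for k in range(1, spec.n_layers + 1):
            cin = sum(spec.layer_channels[i] for i in sorted(spec.links[k]))
            setattr(self, f"layer{k}",
                    nn.ConvBNReLU(cin, spec.layer_channels[k], 3, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        spec = self.spec
        if x.shape[1] != spec.in_channels:
            raise ValueError(
                f"HardBlock expects {spec.in_channels} input channels, "
                f"got {x.shape[1]}")
        outs = [x]
        for k in range(1, spec.n_layers + 1):
            srcs = [outs[i] for i in sorted(spec.links[k])]
            inp = srcs[0] if len(srcs) == 1 else nn.concat(srcs, axis=1)
            outs.append(getattr(self, f"layer{k}")(inp))
        keep = [outs[k] for k in spec.out_layers]
        return keep[0] if len(keep) == 1 else nn.concat(keep, axis=1)


class PlainStage(nn.Module):
    """Ablation baseline: two 3×3 conv-BN-ReLU layers."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.block = nn.Sequential(
            nn.ConvBNReLU(in_channels, out_channels, 3, rng=rng),
            nn.ConvBNReLU(out_channels, out_channels, 3, rng=rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


# ---------------------------------------------------------------------------
# receptive field block
# ---------------------------------------------------------------------------

class RFB(nn.Module):
    """Four-branch receptive field block with a residual shortcut.

    Branches: 1×1; and 1×1 followed by a 3×3 at dilation 1, 3 and 5.  Branch
    outputs are concatenated and fused by a 3×3 convolution; a 1×1 shortcut
    of the input is added before the final activation.
    """

    DILATIONS = (1, 3, 5)

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.branch0 = nn.ConvBNReLU(in_channels, out_channels, 1, rng=rng)
        for i, d in enumerate(self.DILATIONS, start=1):
            setattr(self, f"branch{i}", nn.Sequential(
                nn.ConvBNReLU(in_channels, out_channels, 1, rng=rng),
                nn.ConvBNReLU(out_channels, out_channels, 3, dilation=d,
                              rng=rng),
            ))
        n_branches = 1 + len(self.DILATIONS)
        self.fuse = nn.ConvBNReLU(n_branches * out_channels, out_channels, 3,
                                  relu=False, rng=rng)
        self.shortcut = nn.Conv2d(in_channels, out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"RFB expects {self.in_channels} channels, got {x.shape[1]}")
        branches = [self.branch0(x)] + [
            getattr(self, f"branch{i}")(x)
            for i in range(1, len(self.DILATIONS) + 1)
        ]
        fused = self.fuse(nn.concat(branches, axis=1))
        return (fused + self.shortcut(x)).relu()


class LinearSkip(nn.Module):
    """Ablation stand-in for RFB: a bare 1×1 channel projection."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Conv2d(in_channels, out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.proj(x)


# ---------------------------------------------------------------------------
# multiplicative dense aggregation decoder
# ---------------------------------------------------------------------------

class Aggregator(nn.Module):
    """Fuse three dyadically-spaced scales into logits at the finest one.

    Coarser maps are bilinearly upsampled and combined with the finer
    streams by element-wise multiplication; the fused streams are
    concatenated, transformed by convolution, added to a 1×1 skip projection
    of the finest input, and projected to one channel.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        c = channels
        self.up_a = nn.ConvBNReLU(c, c, 3, rng=rng)
        self.up_b = nn.ConvBNReLU(c, c, 3, rng=rng)
        self.up_c = nn.ConvBNReLU(c, c, 3, rng=rng)
        self.up_d = nn.ConvBNReLU(c, c, 3, rng=rng)
        self.cat_mid = nn.ConvBNReLU(2 * c, 2 * c, 3, rng=rng)
        self.cat_fine = nn.ConvBNReLU(3 * c, 3 * c, 3, rng=rng)
        self.skip = nn.Conv2d(c, 3 * c, 1, rng=rng)
        self.refine = nn.ConvBNReLU(3 * c, 3 * c, 3, rng=rng)
        self.project = nn.Conv2d(3 * c, 1, 1, rng=rng)

    @staticmethod
    def _check_chain(maps: list[Tensor]) -> None:
        if len(maps) < 2:
            raise ValueError("aggregation needs at least two scales")
        for finer, coarser in zip(maps, maps[1:]):
            fh, fw = finer.shape[2:]
            ch, cw = coarser.shape[2:]
            if (ch * 2, cw * 2) != (fh, fw):
                raise ValueError(
                    f"non-dyadic scale chain: {(ch, cw)} must be exactly half "
                    f"of {(fh, fw)}")

    @staticmethod
    def _up2(x: Tensor) -> Tensor:
        return nn.bilinear_resize(x, x.shape[2] * 2, x.shape[3] * 2)

    def forward(self, maps: list[Tensor]) -> Tensor:
        """``maps`` ordered fine → coarse: [1/8, 1/16, 1/32]."""
        self._check_chain(maps)
        x1, x2, x3 = maps  # finest ... coarsest
        x3u = self._up2(x3)
        # multiplicative cross-scale fusion
        h2 = self.up_a(x3u) * x2
        h1 = self.up_b(self._up2(x3u)) * self.up_c(self._up2(x2)) * x1
        # concatenation + conv transform (dense aggregation), then the skip
        mid = self.cat_mid(nn.concat([h2, self.up_d(x3u)], axis=1))
        fine = self.cat_fine(nn.concat([h1, self._up2(mid)], axis=1))
        fused = fine + self.skip(x1)
        return self.project(self.refine(fused))


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    variant: str = "full"
    stem_channels: int = 16
    growth_rates: tuple[int, ...] = (10, 16, 18, 24)
    multiplier: float = 1.7
    layers_per_block: tuple[int, ...] = (4, 4, 8, 8)
    stage_channels: tuple[int, ...] = (32, 48, 64, 96)
    agg_channels: int = 16
    deep_supervision: bool = False
    seed: int = 0

    def validate(self) -> "ModelConfig":
        if self.variant not in VARIANTS:
            raise ValueError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if not (len(self.growth_rates) == len(self.layers_per_block)
                == len(self.stage_channels) == 4):
            raise ValueError("expected 4-stage channel plans")
        return self

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for key in ("growth_rates", "layers_per_block", "stage_channels"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        for key in ("growth_rates", "layers_per_block", "stage_channels"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known).validate()


def hardnet68_like_config(**overrides) -> ModelConfig:
    """A wider preset in the spirit of the HarDNet-68 backbone."""
    base = dict(stem_channels=32, growth_rates=(14, 16, 20, 40),
                multiplier=1.7, layers_per_block=(8, 16, 16, 16),
                stage_channels=(64, 96, 160, 224), agg_channels=32)
    base.update(overrides)
    return ModelConfig(**base).validate()


class VesselSegmenter(nn.Module):
    """Encoder–RFB–aggregation segmentation model (sigmoid probabilities).

    Input images are NCHW float arrays in [0,1]; spatial dims not divisible
    by 32 are zero-padded internally and the output cropped back, so the
    592/1008 working sizes run unchanged.
    """

    GRID = 32

    def __init__(self, config: ModelConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
        c = config
        use_hard = c.variant in ("hard", "full")
        use_rfb = c.variant in ("rfb", "full")

        self.stem1 = nn.ConvBNReLU(3, c.stem_channels, 3, stride=2, rng=rng)
        self.stem2 = nn.ConvBNReLU(c.stem_channels, c.stem_channels, 3,
                                   stride=2, rng=rng)
        in_ch = c.stem_channels
        self.block_specs: list[HardBlockSpec | None] = []
        for i in range(4):
            if use_hard:
                spec = HardBlockSpec.from_rule(
                    c.layers_per_block[i], c.growth_rates[i], c.multiplier,
                    in_ch)
                setattr(self, f"stage{i + 1}", HardBlock(spec, rng))
                block_out = spec.out_channels
                self.block_specs.append(spec)
            else:
                setattr(self, f"stage{i + 1}",
                        PlainStage(in_ch, c.stage_channels[i], rng))
                block_out = c.stage_channels[i]
                self.block_specs.append(None)
            setattr(self, f"trans{i + 1}",
                    nn.ConvBNReLU(block_out, c.stage_channels[i], 1, rng=rng))
            in_ch = c.stage_channels[i]

        skip_cls = RFB if use_rfb else LinearSkip
        # the decoder consumes the three deepest scales (1/8, 1/16, 1/32)
        for i, stage in enumerate((2, 3, 4)):
            setattr(self, f"skip{stage}",
                    skip_cls(c.stage_channels[stage - 1], c.agg_channels, rng))
        self.aggregate = Aggregator(c.agg_channels, rng)
        if c.deep_supervision:
            for stage in (2, 3, 4):
                setattr(self, f"aux{stage}",
                        nn.Conv2d(c.agg_channels, 1, 1, rng=rng))

    # -- helpers ---------------------------------------------------------
    def _pad_input(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        h, w = x.shape[2:]
        ph = (-h) % self.GRID
        pw = (-w) % self.GRID
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        return x, (h, w)

    def forward(self, images) -> Tensor | list[Tensor]:
        """Map an N×3×H×W batch to N×1×H×W vessel probabilities.

        With deep supervision on, returns ``[main, aux2, aux3, aux4]`` — all
        at full resolution.
        """
        if isinstance(images, Tensor):
            images = images.data
        images = np.asarray(images, dtype=np.float32)
        if images.ndim != 4 or images.shape[1] != 3:
            raise ValueError(
                f"expected an N×3×H×W batch, got shape {images.shape}")
        padded, (h, w) = self._pad_input(images)
        x = Tensor(padded)

        x = self.stem2(self.stem1(x))           # 1/4
        taps = []
        for i in range(1, 5):
            x = getattr(self, f"trans{i}")(getattr(self, f"stage{i}")(x))
            if i >= 2:
                taps.append(x)
            if i < 4:
                x = nn.avg_pool2(x)
        # taps: [1/8, 1/16, 1/32] after the pooling layout above
        skips = [getattr(self, f"skip{stage}")(t)
                 for stage, t in zip((2, 3, 4), taps)]
        logits = self.aggregate(skips)          # 1/8 scale
        full = nn.bilinear_resize(logits, padded.shape[2], padded.shape[3])
        main = full[:, :, :h, :w].sigmoid()
        if not self.config.deep_supervision:
            return main
        outs = [main]
        for stage, s in zip((2, 3, 4), skips):
            aux = getattr(self, f"aux{stage}")(s)
            aux = nn.bilinear_resize(aux, padded.shape[2], padded.shape[3])
            outs.append(aux[:, :, :h, :w].sigmoid())
        return outs

    def predict_proba(self, images) -> np.ndarray:
        """Inference helper: eval-mode forward without graph building."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(images)
        finally:
            self.train(was_training)
        if isinstance(out, list):
            out = out[0]
        return out.data


def build_model(config: ModelConfig | dict | None = None,
                **overrides) -> VesselSegmenter:
    if config is None:
        config = ModelConfig()
    elif isinstance(config, dict):
        config = ModelConfig.from_dict(config)
    if overrides:
        d = config.to_dict()
        d.update(overrides)
        config = ModelConfig.from_dict(d)
    return VesselSegmenter(config)


def count_parameters(model: nn.Module) -> int:
    """Number of trainable scalars in the model."""
    return sum(p.data.size for p in model.parameters() if p.requires_grad)


def stage_summary(model: VesselSegmenter) -> list[str]:
    """Human-readable per-stage channel layout for the CLI inspector."""
    c = model.config
    lines = [f"variant: {c.variant}",
             f"stem: 3 -> {c.stem_channels} -> {c.stem_channels} (stride 4)"]
    for i in range(4):
        spec = model.block_specs[i]
        if spec is not None:
            lines.append(
                f"stage {i + 1}: HardBlock layers={spec.n_layers} "
                f"growth={spec.growth_rate} out={spec.out_channels} "
                f"-> transition {c.stage_channels[i]}")
        else:
            lines.append(
                f"stage {i + 1}: PlainStage -> {c.stage_channels[i]}")
    lines.append(
        f"skips ({'RFB' if c.variant in ('rfb', 'full') else 'linear'}): "
        f"-> {c.agg_channels} channels at 1/8, 1/16, 1/32")
    lines.append(f"parameters: {count_parameters(model)}")
    return lines
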