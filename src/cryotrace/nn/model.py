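"""The multimodal encoder–FPN–decoder voxel model.

Two input pathways are fused: the experimental density window (one channel)
passes through a multi-scale convolution block (kernel sizes 3/5/7/9,
concatenated) with channel self-attention, while the 24-channel encoding of
a placed predicted structure passes through a feature convolution gated by
learned feature gates.  The fused 64-channel representation feeds a stack of
three encoder blocks (residual dense block with squeeze-and-excitation, then
dual local/global attention and a transition convolution) of increasing
width, a feature pyramid that harmonizes the three scales to 64 channels
each and concatenates them under softmax-normalized learnable scale weights,
and three cascaded decoders: backbone atoms (4 classes), Cα atoms (4
classes, fed the backbone logits) and amino-acid type (21 classes, fed both
earlier logit sets).

When no predicted structure covers a window the 24-channel input is simply
all zeros and only the density pathway carries signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import ChannelGate, Conv3d, ConvBlock, Module, pick


@dataclass
class ModelConfig:
    window: int = 64
    multiscale_kernels: tuple[int, ...] = (3, 5, 7, 9)
    density_channels: int = 128  # total over the multiscale kernels
    af3_channels: int = 64
    fusion_channels: int = 64
    encoder_channels: tuple[int, int, int] = (128, 256, 512)
    fpn_channels: int = 64  # per scale; concatenation gives 3x this
    decoder_hidden: int = 32
    decoder_out: tuple[int, int, int] = (4, 4, 21)
    dropout: float = 0.01
    downsample_encoders: bool = False
    attention_reduction: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.decoder_out != (4, 4, 21):
            raise ValueError("decoder_out is fixed at (4, 4, 21)")
        if len(self.encoder_channels) != 3:
            raise ValueError("exactly three encoder blocks are required")
        if self.density_channels % len(self.multiscale_kernels):
            raise ValueError(
                "density_channels must divide evenly over the multiscale kernels"
            )

    @classmethod
    def tiny(cls, window: int = 16, seed: int = 0) -> "ModelConfig":
        """A reduced configuration for CPU-scale experiments and tests."""
        return cls(
            window=window,
            density_channels=8,
            af3_channels=8,
            fusion_channels=8,
            encoder_channels=(8, 8, 8),
            fpn_channels=4,
            decoder_hidden=8,
            attention_reduction=2,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("multiscale_kernels", "encoder_channels", "decoder_out"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class DensityBranch(Module):
    """Multi-scale convolutions concatenated, re-weighted by self-attention."""

    def __init__(self, cfg: ModelConfig, rng):
        per = cfg.density_channels // len(cfg.multiscale_kernels)
        self.convs = [ConvBlock(1, per, k, rng) for k in cfg.multiscale_kernels]
        self.attn = ChannelGate(cfg.density_channels, rng, cfg.attention_reduction)

    def __call__(self, x: Tensor) -> Tensor:
        feats = ad.concat([c(x) for c in self.convs], axis=0)
        return ad.mul(feats, self.attn(feats))


class PredictedBranch(Module):
    """Feature convolution of the 24-channel encoding, gated voxel-wise."""

    def __init__(self, cfg: ModelConfig, rng):
        self.feature = ConvBlock(24, cfg.af3_channels, 3, rng)
        self.gate1 = ConvBlock(cfg.af3_channels, cfg.af3_channels, 3, rng)
        self.gate2 = Conv3d(cfg.af3_channels, cfg.af3_channels, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        f = self.feature(x)
        g = ad.sigmoid(self.gate2(self.gate1(f)))
        return ad.mul(f, g)


class EncoderBlock(Module):
    """Residual dense block + SE, dual attention, transition convolution."""

    def __init__(self, cin: int, cout: int, cfg: ModelConfig, rng):
        self.d1 = ConvBlock(cin, cin, 3, rng)
        self.d2 = ConvBlock(2 * cin, cin, 3, rng)
        self.d3 = ConvBlock(3 * cin, cin, 3, rng)
        self.local_fuse = Conv3d(4 * cin, cin, 1, rng)
        self.se = ChannelGate(cin, rng, cfg.attention_reduction)
        self.local_attn = ConvBlock(cin, cin, 3, rng)
        self.global_attn = ChannelGate(cin, rng, cfg.attention_reduction)
        self.transition = ConvBlock(2 * cin, cout, 3, rng)
        self.downsample = cfg.downsample_encoders

    def __call__(self, x: Tensor) -> Tensor:
        # residual dense block: each conv sees all previous feature maps
        x1 = self.d1(x)
        x2 = self.d2(ad.concat([x, x1], axis=0))
        x3 = self.d3(ad.concat([x, x1, x2], axis=0))
        fused = self.local_fuse(ad.concat([x, x1, x2, x3], axis=0))
        rdb = ad.add(ad.mul(fused, self.se(fused)), x)
        # dual attention: local spatial branch + globally gated branch
        local = self.local_attn(rdb)
        gated = ad.mul(rdb, self.global_attn(rdb))
        out = self.transition(ad.concat([local, gated], axis=0))
        if self.downsample:
            out = ad.avg_pool2(out)
        return out


class FPN(Module):
    """Harmonize encoder scales to a uniform width and fuse them.

    Lateral 1×1×1 convolutions map each encoder output to ``fpn_channels``;
    coarser scales (present only when encoder downsampling is enabled) are
    trilinearly upsampled to the finest resolution, smoothed with a 3³
    convolution per scale, weighted by softmax-normalized learnable scalars
    and concatenated.
    """

    def __init__(self, cfg: ModelConfig, rng):
        self.lateral = [Conv3d(c, cfg.fpn_channels, 1, rng) for c in cfg.encoder_channels]
        self.smooth = [ConvBlock(cfg.fpn_channels, cfg.fpn_channels, 3, rng) for _ in range(3)]
        self.scale_logits = ad.parameter(np.zeros(3))

    def __call__(self, enc_feats: list[Tensor], target: tuple[int, int, int]) -> Tensor:
        weights = ad.softmax_vector(self.scale_logits)
        scaled = []
        for i, feat in enumerate(enc_feats):
            f = self.lateral[i](feat)
            if f.shape[1:] != target:
                f = ad.upsample_linear(f, target)
            f = self.smooth[i](f)
            scaled.append(ad.mul(f, pick(weights, i)))
        return ad.concat(scaled, axis=0)


class Decoder(Module):
    """Two-convolution head reducing feature channels to class logits."""

    def __init__(self, cin: int, hidden: int, cout: int, rng):
        self.c1 = ConvBlock(cin, hidden, 3, rng)
        self.c2 = Conv3d(hidden, cout, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x))


class MultiModalNet(Module):
    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.density_branch = DensityBranch(config, rng)
        self.predicted_branch = PredictedBranch(config, rng)
        self.fusion = ConvBlock(
            config.density_channels + config.af3_channels, config.fusion_channels, 3, rng
        )
        chans = [config.fusion_channels, *config.encoder_channels]
        self.encoders = [
            EncoderBlock(chans[i], chans[i + 1], config, rng) for i in range(3)
        ]
        self.fpn = FPN(config, rng)
        fpn_out = 3 * config.fpn_channels
        b, c, a = config.decoder_out
        self.dec_backbone = Decoder(fpn_out, config.decoder_hidden, b, rng)
        self.dec_calpha = Decoder(fpn_out + b, config.decoder_hidden, c, rng)
        self.dec_amino = Decoder(fpn_out + b + c, config.decoder_hidden, a, rng)
        self.training = False
        self._dropout_rng = np.random.default_rng(config.seed + 1)

    def train_mode(self) -> None:
        self.training = True

    def eval_mode(self) -> None:
        self.training = False

    def forward(
        self, density: np.ndarray | Tensor, af3: np.ndarray | Tensor | None
    ) -> tuple[Tensor, Tensor, Tensor]:
        """Run a window through the model.

        ``density``: (D, H, W) scalar window; ``af3``: (24, D, H, W) binary
        encoding or ``None`` (treated as all-zero, the density-only
        fallback).  Returns backbone, Cα and amino-acid logits of channel
        counts (4, 4, 21) at the input spatial shape.
        """
        if not isinstance(density, Tensor):
            density = Tensor(np.asarray(density, dtype=np.float32))
        if density.data.ndim != 3:
            raise ValueError(f"density window must be 3-D, got {density.shape}")
        spatial = density.shape
        if af3 is None:
            af3 = Tensor(np.zeros((24,) + spatial, dtype=np.float32))
        elif not isinstance(af3, Tensor):
            af3 = Tensor(np.asarray(af3, dtype=np.float32))
        if af3.shape != (24,) + spatial:
            raise ValueError(
                f"encoding shape {af3.shape} incompatible with window {spatial}"
            )
        x_density = Tensor(density.data.reshape((1,) + spatial))
        dens = self.density_branch(x_density)
        pred = self.predicted_branch(af3)
        fused = self.fusion(ad.concat([dens, pred], axis=0))
        fused = ad.dropout(fused, self.config.dropout, self._dropout_rng, self.training)
        feats = []
        h = fused
        for enc in self.encoders:
            h = enc(h)
            feats.append(h)
        pyramid = self.fpn(feats, spatial)
        pyramid = ad.dropout(
            pyramid, self.config.dropout, self._dropout_rng, self.training
        )
        logit_b = self.dec_backbone(pyramid)
        logit_c = self.dec_calpha(ad.concat([pyramid, logit_b], axis=0))
        logit_a = self.dec_amino(ad.concat([pyramid, logit_b, logit_c], axis=0))
        return logit_b, logit_c, logit_a


def build_model(config: ModelConfig | None = None) -> MultiModalNet:
    """Construct the multimodal voxel model for a configuration."""
    return MultiModalNet(config or ModelConfig())
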