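"""3D U-Net backbone with re-parameterizable residual (ELANRes) blocks and
multi-scale convolutional attention (MSCA), plus deep-supervision heads.

Architecture overview
---------------------
Four resolution levels.  Each encoder stage is a double 3x3x3 convolution
block (stage 1) or, in the ELANRes variants, an aggregation block whose
sequential re-parameterizable units run at a stage-specific unit width.
Downsampling is a stride-2 convolution on all three axes; upsampling is
trilinear followed by a 3x3x3 convolution.  In the MSCA variants the
bottleneck's convolution block is replaced by a stack of attention blocks
that normalize, project to an attention width, apply four scales of
depthwise 2D convolution slice-wise (5x5 plus 1x7/7x1, 1x11/11x1, 1x21/21x1
strip pairs), mix channels with a 1x1 convolution, gate the projected
features multiplicatively, and finish with a residual MLP.

Deep supervision: auxiliary 1x1x1 heads read the bottleneck and the two
coarser decoder stages (upsampled trilinearly to full resolution); the main
head is a small two-layer 1x1x1 convolution head at full resolution.  In
training mode the forward pass returns all four pre-sigmoid maps (coarsest
first); in eval/deploy mode only the final map.

The default stage widths (62, 130, 158, 248), unit widths (74, 156),
attention width 412, MLP width 872 and head width 67 are the calibrated
configuration whose four ablation variants carry exactly 13,063,192 /
11,449,720 / 14,738,072 / 13,124,600 trainable parameters
(see ``scripts/calibrate_widths.py``).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nn import (Tensor, Module, Sequential, Conv3d, DepthwiseConv2d,
                 BatchNorm3d, ChannelScaleNorm, ReLU, concat)
from .nn.functional import upsample_linear2
from . import reparam

__all__ = ["NetworkConfig", "UNet3D", "build_network", "preset",
           "tiny_config", "PRESET_NAMES", "volume_to_slices",
           "slices_to_volume", "RepUnit", "ELANResBlock", "MSCABlock"]

MSCA_KERNEL_SCALES = ((5, 5), (1, 7), (1, 11), (1, 21))

PRESET_NAMES = ("unet", "msca-unet", "elanres-unet", "elanres-msca-unet")


@dataclass
class NetworkConfig:
    """Full architectural description; the config alone determines the
    trainable parameter count."""

    levels: int = 4
    stage_channels: tuple = (62, 130, 158, 248)
    use_elanres: bool = False
    use_msca: bool = False
    elan_units: int = 4
    elan_hidden: tuple = (74, 156)       # unit width per ELANRes stage (2..levels-1)
    msca_blocks: int = 2
    msca_attn_channels: int = 412
    msca_mlp_channels: int = 872
    msca_kernels: tuple = MSCA_KERNEL_SCALES
    head_hidden: int = 67
    ds_heads: int = 4
    deploy: bool = False

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("need at least 2 resolution levels")
        if len(self.stage_channels) != self.levels:
            raise ValueError("stage_channels must have one width per level")
        if self.ds_heads != self.levels:
            raise ValueError("one deep-supervision head per level is required")
        if tuple(self.msca_kernels) != MSCA_KERNEL_SCALES:
            raise ValueError(
                f"attention kernel scales are fixed to {MSCA_KERNEL_SCALES}")
        if self.use_elanres and len(self.elan_hidden) != self.levels - 2:
            raise ValueError("elan_hidden needs one width per ELANRes stage")

    def to_dict(self) -> dict:
        return {
            "levels": self.levels,
            "stage_channels": list(self.stage_channels),
            "use_elanres": self.use_elanres,
            "use_msca": self.use_msca,
            "elan_units": self.elan_units,
            "elan_hidden": list(self.elan_hidden),
            "msca_blocks": self.msca_blocks,
            "msca_attn_channels": self.msca_attn_channels,
            "msca_mlp_channels": self.msca_mlp_channels,
            "head_hidden": self.head_hidden,
            "ds_heads": self.ds_heads,
            "deploy": self.deploy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("stage_channels", "elan_hidden"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def preset(name: str, **overrides) -> NetworkConfig:
    """One of the four ablation variants by name."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    cfg = NetworkConfig(
        use_elanres="elanres" in name,
        use_msca="msca" in name,
    )
    return replace(cfg, **overrides) if overrides else cfg


def tiny_config(width: int = 8, variant: str = "elanres-msca-unet") -> NetworkConfig:
    """Desk-scale configuration for phantom training (width-8 by default)."""
    c = (width, 2 * width, 4 * width, 8 * width)
    return preset(
        variant,
        stage_channels=c,
        elan_hidden=(width, 2 * width),
        elan_units=2,
        msca_blocks=1,
        msca_attn_channels=8 * width,
        msca_mlp_channels=8 * width,
        head_hidden=width,
    )


# ---------------------------------------------------------------------------
# 3D <-> 2D slice folding
# ---------------------------------------------------------------------------

def volume_to_slices(x: Tensor) -> Tensor:
    """Fold the z (slice) axis of a (B, C, X, Y, Z) grid into the batch axis,
    producing (B*Z, C, X, Y) for slice-wise 2D convolution."""
    B, C, X, Y, Z = x.shape
    return x.transpose((0, 4, 1, 2, 3)).reshape(B * Z, C, X, Y)


def slices_to_volume(x: Tensor, batch_size: int) -> Tensor:
    """Inverse of :func:`volume_to_slices`; ``batch_size`` is the original B."""
    N, C, X, Y = x.shape
    if N % batch_size != 0:
        raise ValueError(
            f"{N} slices cannot be refolded into batches of {batch_size}")
    Z = N // batch_size
    return x.reshape(batch_size, Z, C, X, Y).transpose((0, 2, 3, 4, 1))


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

class ConvBNReLU(Module):
    def __init__(self, cin, cout, kernel=3, stride=1, rng=None):
        super().__init__()
        self.conv = Conv3d(cin, cout, kernel=kernel, stride=stride, rng=rng)
        self.bn = BatchNorm3d(cout)

    def forward(self, x):
        return self.bn(self.conv(x), relu=True)


class DoubleConv(Module):
    """Two 3x3x3 convolutions with batch norm and ReLU."""

    def __init__(self, cin, cout, rng=None):
        super().__init__()
        self.a = ConvBNReLU(cin, cout, rng=rng)
        self.b = ConvBNReLU(cout, cout, rng=rng)

    def forward(self, x):
        return self.b(self.a(x))


class RepUnit(Module):
    """Re-parameterizable unit: parallel 3^3 conv, 1^3 conv and identity,
    each with its own batch norm, summed and rectified.  ``reparameterize``
    collapses the three branches into a single fused 3^3 convolution."""

    def __init__(self, channels, rng=None):
        super().__init__()
        self.channels = channels
        self.deployed = False
        self.conv3 = Conv3d(channels, channels, kernel=3, rng=rng)
        self.bn3 = BatchNorm3d(channels)
        self.conv1 = Conv3d(channels, channels, kernel=1, rng=rng)
        self.bn1 = BatchNorm3d(channels)
        self.bnid = BatchNorm3d(channels)

    def forward(self, x):
        if self.deployed:
            return self.fused(x).relu()
        return (self.bn3(self.conv3(x)) + self.bn1(self.conv1(x))
                + self.bnid(x)).relu()

    def _branches(self):
        def stats(bn):
            return reparam.NormStats(bn.running_mean, bn.running_var,
                                     bn.weight.data, bn.bias.data, bn.eps)

        b3 = reparam.BranchWeights(self.conv3.weight.data,
                                   self.conv3.bias.data, stats(self.bn3))
        b1 = reparam.BranchWeights(self.conv1.weight.data,
                                   self.conv1.bias.data, stats(self.bn1))
        bid = reparam.identity_branch(self.channels, stats(self.bnid))
        return [b3, b1, bid]

    def reparameterize(self):
        if self.deployed:
            return
        merged = reparam.merge_branches(
            [reparam.fuse_norm(b) for b in self._branches()], target_size=3)
        fused = Conv3d(self.channels, self.channels, kernel=3)
        fused.weight.data = merged.kernel.astype(np.float32)
        fused.bias.data = merged.bias.astype(np.float32)
        for name in ("conv3", "bn3", "conv1", "bn1", "bnid"):
            delattr(self, name)
        self.fused = fused
        object.__setattr__(self, "deployed", True)


class ELANResBlock(Module):
    """Aggregation block: a 1x1x1 stem widens/splits the input, sequential
    re-parameterizable units transform one half, the pass-through half and
    every unit output are concatenated and fused back by a 1x1x1 convolution,
    and the block output adds a residual of its input (projected when the
    channel counts differ)."""

    def __init__(self, cin, cout, hidden, units, rng=None):
        super().__init__()
        self.hidden = hidden
        self.stem = Conv3d(cin, 2 * hidden, kernel=1, rng=rng)
        self.stem_bn = BatchNorm3d(2 * hidden)
        self.units = Sequential(*[RepUnit(hidden, rng=rng) for _ in range(units)])
        self.fuse = Conv3d((units + 1) * hidden, cout, kernel=1, rng=rng)
        self.fuse_bn = BatchNorm3d(cout)
        if cin != cout:
            self.short = Conv3d(cin, cout, kernel=1, rng=rng)
            self.short_bn = BatchNorm3d(cout)
        else:
            self.short = None

    def forward(self, x):
        s = self.stem_bn(self.stem(x)).relu()
        h = self.hidden
        keep, work = s[:, :h], s[:, h:]
        outs = [keep]
        for unit in self.units:
            work = unit(work)
            outs.append(work)
        fused = self.fuse_bn(self.fuse(concat(outs, axis=1)))
        res = x if self.short is None else self.short_bn(self.short(x))
        return (fused + res).relu()


class MSCABlock(Module):
    """Multi-scale convolutional attention with a residual MLP.

    Normalize -> project to the attention width -> depthwise 5x5 base
    convolution -> three strip-convolution pairs (1x7/7x1, 1x11/11x1,
    1x21/21x1) applied to the base output and summed with it -> 1x1 channel
    mixing -> multiplicative gating of the projected features -> project
    back -> residual; then norm -> pointwise MLP -> residual.  The depthwise
    convolutions are 2D and run slice-wise via the 3D-to-2D transform.
    """

    def __init__(self, channels, attn_channels, mlp_channels, rng=None):
        super().__init__()
        d = attn_channels
        self.norm1 = ChannelScaleNorm(channels)
        self.proj_in = Conv3d(channels, d, kernel=1, rng=rng)
        self.dw5 = DepthwiseConv2d(d, (5, 5), rng=rng)
        self.s7a = DepthwiseConv2d(d, (1, 7), rng=rng)
        self.s7b = DepthwiseConv2d(d, (7, 1), rng=rng)
        self.s11a = DepthwiseConv2d(d, (1, 11), rng=rng)
        self.s11b = DepthwiseConv2d(d, (11, 1), rng=rng)
        self.s21a = DepthwiseConv2d(d, (1, 21), rng=rng)
        self.s21b = DepthwiseConv2d(d, (21, 1), rng=rng)
        self.mix = Conv3d(d, d, kernel=1, rng=rng)
        self.proj_out = Conv3d(d, channels, kernel=1, rng=rng)
        self.norm2 = ChannelScaleNorm(channels)
        self.mlp_a = Conv3d(channels, mlp_channels, kernel=1, rng=rng)
        self.mlp_b = Conv3d(mlp_channels, channels, kernel=1, rng=rng)

    def forward(self, x):
        B = x.shape[0]
        a = self.proj_in(self.norm1(x)).gelu()
        a2 = volume_to_slices(a)
        base = self.dw5(a2)
        attn2 = (base + self.s7b(self.s7a(base))
                 + self.s11b(self.s11a(base))
                 + self.s21b(self.s21a(base)))
        attn = self.mix(slices_to_volume(attn2, B))
        x = x + self.proj_out(attn * a)
        return x + self.mlp_b(self.mlp_a(self.norm2(x)).gelu())


class Upsample2(Module):
    def forward(self, x):
        return upsample_linear2(x, axes=(2, 3, 4))


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class UNet3D(Module):
    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.stage_channels
        L = config.levels

        def stage_block(cin, cout, level):
            # ELANRes occupies every non-full-resolution stage
            if config.use_elanres and level >= 1:
                h = config.elan_hidden[level - 1]
                return ELANResBlock(cin, cout, h, config.elan_units, rng=rng)
            return DoubleConv(cin, cout, rng=rng)

        self.enc = Sequential(*[
            stage_block(1 if k == 0 else ch[k], ch[k], k)
            for k in range(L - 1)])
        self.down = Sequential(*[
            ConvBNReLU(ch[k], ch[k + 1], stride=2, rng=rng)
            for k in range(L - 1)])
        if config.use_msca:
            self.bottleneck = Sequential(*[
                MSCABlock(ch[-1], config.msca_attn_channels,
                          config.msca_mlp_channels, rng=rng)
                for _ in range(config.msca_blocks)])
        else:
            self.bottleneck = DoubleConv(ch[-1], ch[-1], rng=rng)
        self.up = Sequential(*[
            Sequential(Upsample2(), ConvBNReLU(ch[k + 1], ch[k], rng=rng))
            for k in reversed(range(L - 1))])
        self.dec = Sequential(*[
            stage_block(2 * ch[k], ch[k], k)
            for k in reversed(range(L - 1))])
        # deep-supervision heads: bottleneck + coarse decoder stages
        self.aux = Sequential(*[
            Conv3d(ch[k], 1, kernel=1, rng=rng)
            for k in reversed(range(2, L))] + [
            Conv3d(ch[1], 1, kernel=1, rng=rng)])
        self.head = Sequential(Conv3d(ch[0], config.head_hidden, kernel=1,
                                      rng=rng),
                               ReLU(),
                               Conv3d(config.head_hidden, 1, kernel=1,
                                      rng=rng))

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        L = self.config.levels
        div = 2 ** (L - 1)
        if any(s % div for s in x.shape[2:]):
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by {div} "
                f"for a {L}-level network")
        skips = []
        h = x
        for k in range(L - 1):
            if k > 0:
                h = self.down.layers[k - 1](h)
            h = self.enc.layers[k](h)
            skips.append(h)
        h = self.down.layers[L - 2](h)
        h = self.bottleneck(h)
        ds_inputs = [h]
        for i in range(L - 1):
            h = self.up.layers[i](h)
            h = self.dec.layers[i](concat([h, skips[L - 2 - i]], axis=1))
            if i < L - 2:
                ds_inputs.append(h)
        final = self.head(h)
        if not self.training or self.config.deploy:
            return final
        outs = []
        # aux heads indexed coarsest-first; upsample each to full resolution
        heads = [self.aux.layers[0]] + list(self.aux.layers[1:])
        for i, (feat, head) in enumerate(zip(ds_inputs, heads)):
            o = head(feat)
            for _ in range(L - 1 - i):
                o = upsample_linear2(o, axes=(2, 3, 4))
            outs.append(o)
        outs.append(final)
        return outs


def settle_norm_stats(model: Module, x, passes: int = 2) -> Module:
    """Adopt realistic batch-norm running statistics from forward passes.

    Freshly initialized running statistics (mean 0, variance 1) bear no
    relation to the network's actual activation distribution, which makes
    eval-mode activations drift to large magnitudes with depth.  One pass
    with momentum 1 adopts the batch statistics outright; further passes
    refine them under the configured momentum.
    """
    from .nn import no_grad  # local import to avoid cycle at module load

    if not isinstance(x, Tensor):
        x = Tensor(x)
    model.train()
    bns = [m for m in model.modules() if isinstance(m, BatchNorm3d)]
    saved = [bn.momentum for bn in bns]
    with no_grad():
        for i in range(passes):
            for bn in bns:
                bn.momentum = 1.0 if i == 0 else 0.5
            model(x)
    for bn, mom in zip(bns, saved):
        bn.momentum = mom
    model.eval()
    return model


def build_network(config: NetworkConfig, seed: int = 0) -> UNet3D:
    """Instantiate the network; the forward contract and parameter count are
    fully determined by ``config``."""
    model = UNet3D(config, seed=seed)
    if config.deploy:
        config.deploy = False
        reparam.convert_to_deploy(model)
    return model
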