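"""Local-enhancement encoder-decoder segmentation network.

The local enhancement (LE) block is an ASPP-style multi-branch unit tuned
toward nearby context: a 1x1 convolution, four 3x3 depthwise-separable
convolutions with dilation rates (1, 6, 12, 18), and a global-average-pool
branch, all emitting the same channel width.  The six branch outputs are
concatenated (X_t4, 6x the branch width) and a 3x3 depthwise-separable
convolution reduces the channels back to one-sixth (X_t5).

Three network variants share the same encoder and classifier interface:

``base``
    Encoder plus a plain decoder: each stage is a 3x3 stride-2 transposed
    convolution followed by a 3x3 convolution.
``base_le``
    One LE block on the lowest-resolution encoder feature, then the plain
    decoder.
``base_le_decoder``
    An LE block inside every decoder stage; its output is upsampled x2,
    concatenated with the encoder skip feature at twice the resolution
    (X_t6), refined by a 3x3 convolution (X_t7) and a 1x1 convolution
    (X_{t+1}), with batch-norm + ReLU after each of those last three
    convolutions.

Every decoder stage carries an auxiliary 1x1 classifier head (used only for
deep supervision during training); the main head follows the last stage and
is bilinearly upsampled to the input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import functional as F
from .nn.autograd import Tensor, as_tensor
from .nn.modules import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Module,
    ReLU,
    Sequential,
)

VARIANTS = ("base", "base_le", "base_le_decoder")
ENCODERS = ("tiny", "resnet50-style", "resnet152-style")

__all__ = [
    "FeatureMap",
    "LEConfig",
    "NetworkConfig",
    "DepthwiseSeparableConv",
    "LEModule",
    "DecoderFuse",
    "Network",
    "build_network",
    "network_forward",
    "ds_dilated_conv",
    "le_forward",
    "decoder_fuse",
    "VARIANTS",
    "ENCODERS",
]


@dataclass
class FeatureMap:
    """A C x H x W feature array flowing through the network."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"feature map must be (C, H, W), got {self.values.shape}")
        if min(self.values.shape) < 1:
            raise ValueError("feature map dimensions must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite values")

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def height(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class LEConfig:
    in_channels: int
    branch_channels: int
    dilation_rates: tuple[int, ...] = (1, 6, 12, 18)

    def __post_init__(self):
        if self.branch_channels < 1 or self.in_channels < 1:
            raise ValueError("channel counts must be >= 1")
        rates = self.dilation_rates
        if rates[0] != 1 or any(a >= b for a, b in zip(rates, rates[1:])):
            raise ValueError("dilation rates must be strictly increasing and start at 1")


@dataclass(frozen=True)
class NetworkConfig:
    num_classes: int = 3
    encoder: str = "tiny"
    encoder_output_stride: int = 16
    n_decoder_stages: int = 2
    variant: str = "base_le_decoder"
    aux_weights: tuple[float, ...] = (0.2, 0.3)
    branch_channels: int | None = None  # None -> 32 tiny, 256 resnet
    dilation_rates: tuple[int, ...] = (1, 6, 12, 18)
    pad_to_stride: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; pick from {VARIANTS}")
        if self.encoder not in ENCODERS:
            raise ValueError(f"unknown encoder {self.encoder!r}; pick from {ENCODERS}")
        if self.n_decoder_stages < 1:
            raise ValueError("need at least one decoder stage")
        if len(self.aux_weights) != self.n_decoder_stages:
            raise ValueError("one auxiliary weight per decoder stage required")
        if any(a > b for a, b in zip(self.aux_weights, self.aux_weights[1:])):
            raise ValueError("auxiliary weights must be non-decreasing with stage depth")
        if self.encoder_output_stride < 2**self.n_decoder_stages:
            raise ValueError("output stride too small for the decoder depth")

    @property
    def resolved_branch_channels(self) -> int:
        if self.branch_channels is not None:
            return self.branch_channels
        return 32 if self.encoder == "tiny" else 256


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class ConvBNReLU(Sequential):
    def __init__(self, cin, cout, k, *, stride=1, dilation=1, rng=None):
        pad = dilation * (k - 1) // 2
        super().__init__(
            Conv2d(cin, cout, k, stride=stride, padding=pad, dilation=dilation,
                   bias=False, rng=rng),
            BatchNorm2d(cout),
            ReLU(),
        )


class DepthwiseSeparableConv(Module):
    """Per-channel 3x3 (optionally dilated) convolution + 1x1 channel mixing."""

    def __init__(self, in_channels, out_channels, *, dilation=1, use_bn=True, rng=None):
        super().__init__()
        self.depthwise = Conv2d(
            in_channels, in_channels, 3,
            padding=dilation, dilation=dilation, groups=in_channels,
            bias=not use_bn, rng=rng,
        )
        self.pointwise = Conv2d(in_channels, out_channels, 1, bias=not use_bn, rng=rng)
        self.norm = Sequential(BatchNorm2d(out_channels), ReLU()) if use_bn else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.pointwise(self.depthwise(x))
        return self.norm(x) if self.norm is not None else x


class LEModule(Module):
    """The local enhancement block (six branches + one-sixth reduction)."""

    def __init__(self, cfg: LEConfig, *, use_bn: bool = True, rng=None):
        super().__init__()
        self.cfg = cfg
        cin, bc = cfg.in_channels, cfg.branch_channels

        def maybe_norm(cout):
            return Sequential(BatchNorm2d(cout), ReLU()) if use_bn else None

        self.conv1x1 = Conv2d(cin, bc, 1, bias=not use_bn, rng=rng)
        self.conv1x1_norm = maybe_norm(bc)
        self.dilated = [
            DepthwiseSeparableConv(cin, bc, dilation=r, use_bn=use_bn, rng=rng)
            for r in cfg.dilation_rates
        ]
        self.pool_conv = Conv2d(cin, bc, 1, bias=not use_bn, rng=rng)
        self.pool_norm = maybe_norm(bc)
        n_branches = 2 + len(cfg.dilation_rates)
        self.reduce = DepthwiseSeparableConv(
            n_branches * bc, bc, dilation=1, use_bn=use_bn, rng=rng
        )

    def forward(self, x: Tensor, return_concat: bool = False):
        x = as_tensor(x)
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"LE expects {self.cfg.in_channels} input channels, got {x.shape[1]}"
            )
        h, w = x.shape[-2:]
        b1 = self.conv1x1(x)  # X_t1
        if self.conv1x1_norm is not None:
            b1 = self.conv1x1_norm(b1)
        dilated = [m(x) for m in self.dilated]  # X_t2 (four maps)
        pooled = self.pool_conv(F.spatial_mean(x))  # X_t3
        if self.pool_norm is not None:
            pooled = self.pool_norm(pooled)
        pooled = F.broadcast_spatial(pooled, h, w)
        x_t4 = F.concat([b1, *dilated, pooled], axis=1)
        x_t5 = self.reduce(x_t4)
        return (x_t5, x_t4) if return_concat else x_t5


class DecoderFuse(Module):
    """x2 upsample of X_t5, concat with skip C_t, 3x3 conv -> X_t7, 1x1 -> X_{t+1}."""

    def __init__(self, in_channels, skip_channels, num_out, *, rng=None):
        super().__init__()
        self.conv3x3 = ConvBNReLU(in_channels + skip_channels, num_out, 3, rng=rng)
        self.conv1x1 = ConvBNReLU(num_out, num_out, 1, rng=rng)

    def forward(self, x_t5: Tensor, c_t: Tensor, return_mid: bool = False):
        x_t5, c_t = as_tensor(x_t5), as_tensor(c_t)
        h, w = x_t5.shape[-2:]
        if c_t.shape[-2:] != (2 * h, 2 * w):
            raise ValueError(
                f"skip resolution {c_t.shape[-2:]} must be exactly twice {x_t5.shape[-2:]}"
            )
        up = F.bilinear_resize(x_t5, 2 * h, 2 * w)
        x_t6 = F.concat([up, c_t], axis=1)
        x_t7 = self.conv3x3(x_t6)
        x_next = self.conv1x1(x_t7)
        return (x_next, x_t7) if return_mid else x_next


class PlainDecoderStage(Module):
    """3x3 stride-2 transposed convolution + 3x3 convolution (the Base decoder)."""

    def __init__(self, in_channels, out_channels, *, rng=None):
        super().__init__()
        self.deconv = ConvTranspose2d(in_channels, out_channels, 3, rng=rng)
        self.deconv_norm = Sequential(BatchNorm2d(out_channels), ReLU())
        self.conv = ConvBNReLU(out_channels, out_channels, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(self.deconv_norm(self.deconv(x)))


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

class TinyEncoder(Module):
    """Four stride-2 conv stages (widths 16/32/64/128) -> output stride 16.

    The desk-scale default: small enough to train on a CPU in seconds while
    exercising every architectural element.
    """

    widths = (16, 32, 64, 128)

    def __init__(self, in_channels=1, *, rng=None):
        super().__init__()
        w = self.widths
        self.stages = [
            ConvBNReLU(in_channels, w[0], 3, stride=2, rng=rng),  # OS2
            ConvBNReLU(w[0], w[1], 3, stride=2, rng=rng),         # OS4
            ConvBNReLU(w[1], w[2], 3, stride=2, rng=rng),         # OS8
            ConvBNReLU(w[2], w[3], 3, stride=2, rng=rng),         # OS16
        ]
        self.out_channels = {2: w[0], 4: w[1], 8: w[2], 16: w[3]}

    def forward(self, x: Tensor) -> dict[int, Tensor]:
        feats, os = {}, 1
        for stage in self.stages:
            x = stage(x)
            os *= 2
            feats[os] = x
        return feats


class Bottleneck(Module):
    expansion = 4

    def __init__(self, cin, width, *, stride=1, dilation=1, rng=None):
        super().__init__()
        cout = width * self.expansion
        self.conv1 = ConvBNReLU(cin, width, 1, rng=rng)
        self.conv2 = ConvBNReLU(width, width, 3, stride=stride, dilation=dilation, rng=rng)
        self.conv3 = Sequential(
            Conv2d(width, cout, 1, bias=False, rng=rng), BatchNorm2d(cout)
        )
        if stride != 1 or cin != cout:
            self.shortcut = Sequential(
                Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
                BatchNorm2d(cout),
            )
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.conv3(self.conv2(self.conv1(x)))
        skip = self.shortcut(x) if self.shortcut is not None else x
        return F.relu(F.add(out, skip))


class ResNetEncoder(Module):
    """Bottleneck-stack encoder in the ResNet lineage, output stride 16.

    ``depths`` (3,4,6,3) gives the 50-layer flavour; (3,8,36,3) the
    152-layer one.  The final stack runs at stride 1 with dilation 2 so the
    deepest feature stays at OS16.
    """

    def __init__(self, depths, in_channels=1, base_width=64, *, rng=None):
        super().__init__()
        self.stem = ConvBNReLU(in_channels, base_width, 3, stride=2, rng=rng)  # OS2
        widths = [base_width * 2**i for i in range(4)]
        strides = (2, 2, 2, 1)
        dilations = (1, 1, 1, 2)
        cin = base_width
        self.stacks = []
        for depth, width, stride, dil in zip(depths, widths, strides, dilations):
            blocks = []
            for b in range(depth):
                blocks.append(
                    Bottleneck(cin, width, stride=stride if b == 0 else 1,
                               dilation=dil, rng=rng)
                )
                cin = width * Bottleneck.expansion
            self.stacks.append(Sequential(*blocks))
        e = Bottleneck.expansion
        self.out_channels = {2: base_width, 4: widths[0] * e, 8: widths[1] * e,
                             16: widths[3] * e}

    def forward(self, x: Tensor) -> dict[int, Tensor]:
        x = self.stem(x)
        feats = {2: x}
        x = self.stacks[0](x)
        feats[4] = x
        x = self.stacks[1](x)
        feats[8] = x
        x = self.stacks[2](x)
        x = self.stacks[3](x)
        feats[16] = x
        return feats


def _make_encoder(cfg: NetworkConfig, rng) -> Module:
    if cfg.encoder == "tiny":
        return TinyEncoder(rng=rng)
    depths = (3, 4, 6, 3) if cfg.encoder == "resnet50-style" else (3, 8, 36, 3)
    return ResNetEncoder(depths, rng=rng)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class Network(Module):
    def __init__(self, cfg: NetworkConfig, *, rng=None):
        super().__init__()
        if cfg.encoder_output_stride != 16:
            raise ValueError("encoders are built for output stride 16")
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.encoder = _make_encoder(cfg, rng)
        bc = cfg.resolved_branch_channels
        deep_ch = self.encoder.out_channels[cfg.encoder_output_stride]

        self.pre_le = None
        if cfg.variant == "base_le":
            self.pre_le = LEModule(LEConfig(deep_ch, bc, cfg.dilation_rates), rng=rng)
            deep_ch = bc

        self.stage_les, self.stage_fuses, self.plain_stages = [], [], []
        self.aux_heads = []
        cur_ch, cur_os = deep_ch, cfg.encoder_output_stride
        for _ in range(cfg.n_decoder_stages):
            skip_os = cur_os // 2
            if cfg.variant == "base_le_decoder":
                self.stage_les.append(
                    LEModule(LEConfig(cur_ch, bc, cfg.dilation_rates), rng=rng)
                )
                self.stage_fuses.append(
                    DecoderFuse(bc, self.encoder.out_channels[skip_os], bc, rng=rng)
                )
            else:
                self.plain_stages.append(PlainDecoderStage(cur_ch, bc, rng=rng))
            self.aux_heads.append(Conv2d(bc, cfg.num_classes, 1, rng=rng))
            cur_ch, cur_os = bc, skip_os
        self.main_head = Conv2d(cur_ch, cfg.num_classes, 1, rng=rng)
        self.final_os = cur_os

    def forward(self, x: Tensor):
        """Return ``(main_logits, [aux_logits...])`` at input resolution / stage resolutions."""
        x = as_tensor(x)
        if x.ndim != 4:
            raise ValueError(f"expected (N, C, H, W) batch, got shape {x.shape}")
        n, _, h, w = x.shape
        os = self.cfg.encoder_output_stride
        pad_h = (-h) % os
        pad_w = (-w) % os
        if (pad_h or pad_w) and not self.cfg.pad_to_stride:
            raise ValueError(
                f"input {h}x{w} not divisible by output stride {os}; "
                "set pad_to_stride=True to zero-pad"
            )
        if pad_h or pad_w:
            x = Tensor(np.pad(x.data, ((0, 0), (0, 0), (0, pad_h), (0, pad_w))),
                       parents=((x, lambda g: g[:, :, :h, :w]),))
        feats = self.encoder(x)
        cur = feats[os]
        if self.pre_le is not None:
            cur = self.pre_le(cur)
        aux = []
        cur_os = os
        for t in range(self.cfg.n_decoder_stages):
            skip_os = cur_os // 2
            if self.cfg.variant == "base_le_decoder":
                x_t5 = self.stage_les[t](cur)
                cur, x_t7 = self.stage_fuses[t](x_t5, feats[skip_os], return_mid=True)
                aux.append(self.aux_heads[t](x_t7))
            else:
                cur = self.plain_stages[t](cur)
                aux.append(self.aux_heads[t](cur))
            cur_os = skip_os
        logits = self.main_head(cur)
        main = F.bilinear_resize(logits, h + pad_h, w + pad_w)
        if pad_h or pad_w:
            main = Tensor(main.data[:, :, :h, :w],
                          parents=((main, lambda g: np.pad(
                              g, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)))),))
        return main, aux

    def predict(self, x) -> np.ndarray:
        """Argmax class map from the main head (aux heads ignored)."""
        was_training = self.training
        self.eval()
        try:
            main, _ = self.forward(as_tensor(x))
        finally:
            self.train(was_training)
        return np.argmax(main.data, axis=1)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_network(cfg: NetworkConfig, seed: int = 0) -> Network:
    """Construct a network with weights drawn deterministically from ``seed``."""
    return Network(cfg, rng=np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE))))


def network_forward(net: Network, batch):
    """Spec-level forward: (main, aux) in training mode, main only in eval."""
    main, aux = net(as_tensor(batch))
    return (main, aux) if net.training else main


# ---------------------------------------------------------------------------
# functional entry points (operate on plain arrays; used by tests/oracles)
# ---------------------------------------------------------------------------

def _as_batch(x) -> tuple[np.ndarray, bool]:
    arr = x.values if isinstance(x, FeatureMap) else np.asarray(x, dtype=np.float64)
    if arr.ndim == 3:
        return arr[None], True
    if arr.ndim == 4:
        return arr, False
    raise ValueError(f"expected (C,H,W) or (N,C,H,W), got {arr.shape}")


def ds_dilated_conv(x, depthwise_weights, pointwise_weights, rate: int,
                    depthwise_bias=None, pointwise_bias=None) -> np.ndarray:
    """Depthwise 3x3 dilated convolution + 1x1 pointwise mixing on raw arrays.

    ``depthwise_weights`` is (C, 1, 3, 3); ``pointwise_weights`` is
    (C_out, C, 1, 1).  Zero "same" padding preserves the spatial dims.
    """
    if rate < 1:
        raise ValueError("dilation rate must be >= 1")
    arr, squeeze = _as_batch(x)
    c = arr.shape[1]
    dw = np.asarray(depthwise_weights, dtype=np.float64)
    pw = np.asarray(pointwise_weights, dtype=np.float64)
    if dw.shape != (c, 1, 3, 3):
        raise ValueError(f"depthwise weights must be ({c},1,3,3), got {dw.shape}")
    mid = F.conv2d(Tensor(arr), Tensor(dw),
                   None if depthwise_bias is None else Tensor(depthwise_bias),
                   padding=rate, dilation=rate, groups=c)
    out = F.conv2d(mid, Tensor(pw),
                   None if pointwise_bias is None else Tensor(pointwise_bias))
    return out.data[0] if squeeze else out.data


def le_forward(x_t, cfg_or_module, seed: int = 0) -> np.ndarray:
    """Run an LE block over a raw feature array (X_t -> X_t5)."""
    module = (
        cfg_or_module
        if isinstance(cfg_or_module, LEModule)
        else LEModule(cfg_or_module, rng=np.random.default_rng(seed))
    )
    arr, squeeze = _as_batch(x_t)
    module.eval()
    out = module(Tensor(arr))
    return out.data[0] if squeeze else out.data


def decoder_fuse(x_t5, c_t, num_out: int, seed: int = 0) -> np.ndarray:
    """Run a decoder fusion stage over raw feature arrays (X_t5, C_t -> X_{t+1})."""
    a, squeeze = _as_batch(x_t5)
    b, _ = _as_batch(c_t)
    module = DecoderFuse(a.shape[1], b.shape[1], num_out,
                         rng=np.random.default_rng(seed))
    module.eval()
    out = module(Tensor(a), Tensor(b))
    return out.data[0] if squeeze else out.data
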