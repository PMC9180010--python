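"""MVDNet architecture: LAB encoder, FFM decoder, and the full network.

The network is a lightweight U-shaped encoder-decoder for multi-class
segmentation of surgical scenes.  The encoder downsamples three times
(to 1/2, 1/4, 1/8 resolution) with strided 3x3 convolutions and runs a
Light Asymmetric Bottleneck (LAB) block at each scale; the decoder
restores resolution with three Feature Fusion Modules (FFM) and a final
1x1 classifier followed by 2x bilinear upsampling.

A LAB module is a pre-activated residual bottleneck: a 1x1 convolution
halves the channels, a 3x1 and a 1x3 depthwise *dilated* convolution
factorize a 3x3 spatial filter at O(N) cost per pixel, and a final 1x1
pointwise convolution (no trailing nonlinearity) restores the channel
count before the residual addition.

An FFM squeezes the low-level (high-resolution) features into a
single-channel spatial attention map - 1x1 conv, BN, channel-wise
average pooling, sigmoid - multiplies it with the 3x3-convolved
high-level features, and adds the high-level features back:

    F = PReLU(BN( sigma(AvgPool_c(BN(f1x1(F_L)))) (x) f3x3(F_H) + f3x3(F_H) ))

At every stage boundary the block input, block output and an
average-pooled copy of the input image are concatenated before the next
3x3 convolution (the stride-2 downsampler after stages 1-2, the first
FFM's high-branch convolution after stage 3).  The two concatenation
sources are individually togglable for ablations.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

from .errors import InvalidInputError, InvalidSpecError, ShapeError
from .nn import (
    AvgPool2x2,
    BatchNorm2d,
    ChannelMean,
    Conv2d,
    Module,
    PReLU,
    Sequential,
    Sigmoid,
    UpsampleBilinear2x,
)

__all__ = [
    "FeatureMapSpec",
    "LABSpec",
    "SeparableKernel",
    "FFMSpec",
    "MVDNetSpec",
    "compose_1d_kernels",
    "LABModule",
    "FFMModule",
    "MVDNet",
    "build_mvdnet",
    "mvdnet_forward",
    "lab_forward",
    "ffm_forward",
]

ALLOWED_DILATIONS = (1, 2, 4, 8, 16)


@dataclass(frozen=True)
class FeatureMapSpec:
    """Channel count and spatial size of one feature map."""

    channels: int
    height: int
    width: int

    def __post_init__(self):
        if min(self.channels, self.height, self.width) < 1:
            raise InvalidSpecError("feature map dimensions must all be >= 1")


@dataclass(frozen=True)
class LABSpec:
    """One LAB module: channel count and dilation rate."""

    channels: int
    dilation: int = 1

    def __post_init__(self):
        if self.channels % 2:
            raise InvalidSpecError(f"LAB channels must be even, got {self.channels}")
        if self.dilation not in ALLOWED_DILATIONS:
            raise InvalidSpecError(f"dilation must be one of {ALLOWED_DILATIONS}")

    @property
    def bottleneck_channels(self) -> int:
        return self.channels // 2


@dataclass
class SeparableKernel:
    """A rank-1 separable kernel given by its two 1-D factors.

    Convolving with ``vertical`` (n x 1) then ``horizontal`` (1 x n),
    with no intervening nonlinearity, equals convolving once with the
    outer product ``v . h^T``.
    """

    horizontal: np.ndarray
    vertical: np.ndarray
    size: int
    input_maps: int = 1
    output_maps: int = 1
    bias_h: float = 0.0
    bias_v: float = 0.0


def compose_1d_kernels(k: SeparableKernel) -> np.ndarray:
    """Compose the two 1-D factors into the equivalent n x n kernel."""
    h = np.asarray(k.horizontal, dtype=float).reshape(-1)
    v = np.asarray(k.vertical, dtype=float).reshape(-1)
    if h.size != k.size or v.size != k.size:
        raise InvalidSpecError(
            f"1-D factor lengths ({v.size}, {h.size}) do not match size {k.size}"
        )
    return np.outer(v, h)


@dataclass(frozen=True)
class FFMSpec:
    """Channel bookkeeping of one feature fusion module."""

    low_channels: int
    high_channels: int
    upsample_high: bool
    channel_pool: bool = True

    @property
    def output_channels(self) -> int:
        return self.low_channels


@dataclass
class MVDNetSpec:
    """Declarative description of the network; defaults give the full model."""

    stage_channels: tuple[int, int, int] = (32, 64, 128)
    depths: tuple[int, int, int] = (2, 4, 4)
    dilations: tuple[int, int, int] = (2, 4, 8)
    num_classes: int = 10
    use_image_injection: bool = True
    use_block_concat: bool = True
    use_ffm: bool = True
    ffm_channel_pool: bool = True
    first_conv_dilation: int = 1

    def __post_init__(self):
        self.stage_channels = tuple(int(c) for c in self.stage_channels)
        self.depths = tuple(int(d) for d in self.depths)
        self.dilations = tuple(int(r) for r in self.dilations)
        self.validate()

    def validate(self) -> None:
        if len(self.stage_channels) != 3 or len(self.depths) != 3 or len(self.dilations) != 3:
            raise InvalidSpecError("stage_channels, depths and dilations must be triples")
        if any(d < 1 for d in self.depths):
            raise InvalidSpecError(f"depths must all be >= 1, got {self.depths}")
        if any(c < 2 or c % 2 for c in self.stage_channels):
            raise InvalidSpecError("stage channels must be even and >= 2")
        if any(r not in ALLOWED_DILATIONS for r in self.dilations):
            raise InvalidSpecError(f"dilations must be in {ALLOWED_DILATIONS}")
        if self.num_classes < 2:
            raise InvalidSpecError("need at least two classes")
        if self.first_conv_dilation < 1:
            raise InvalidSpecError("first_conv_dilation must be >= 1")

    # -- stage-boundary channel bookkeeping ---------------------------
    def boundary_channels(self, stage: int) -> int:
        """Channels entering the 3x3 conv that closes encoder stage ``stage``."""
        c = self.stage_channels[stage]
        total = c
        if self.use_block_concat:
            total += c
        if self.use_image_injection:
            total += 3
        return total

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "MVDNetSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidSpecError(f"unknown spec fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        d = self.to_dict()
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "MVDNetSpec":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        elif isinstance(source, str) and "\n" in source:
            d = yaml.safe_load(io.StringIO(source))
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "MVDNetSpec":
        return cls.from_dict(json.loads(text))

    def with_(self, **kw) -> "MVDNetSpec":
        return replace(self, **kw)


class LABModule(Module):
    """Pre-activated light asymmetric bottleneck with residual connection.

    Layer order: BN-PReLU-1x1 conv (C -> C/2), BN-PReLU-3x1 depthwise
    dilated conv, BN-PReLU-1x3 depthwise dilated conv, 1x1 pointwise
    conv (C/2 -> C, no pre-activation and no trailing nonlinearity),
    then addition of the input.  Convolutions feeding a BN carry no
    bias; the 1x3 depthwise conv and the final pointwise conv do.
    """

    def __init__(self, spec: LABSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        C, r = spec.channels, spec.dilation
        c = spec.bottleneck_channels
        self.spec = spec
        self.bn1 = BatchNorm2d(C)
        self.act1 = PReLU(C)
        self.conv_reduce = Conv2d(C, c, 1, rng=rng)
        self.bn2 = BatchNorm2d(c)
        self.act2 = PReLU(c)
        self.conv_v = Conv2d(c, c, (3, 1), dilation=r, groups=c, rng=rng)
        self.bn3 = BatchNorm2d(c)
        self.act3 = PReLU(c)
        self.conv_h = Conv2d(c, c, (1, 3), dilation=r, groups=c, bias=True, rng=rng)
        self.conv_expand = Conv2d(c, C, 1, bias=True, rng=rng)
        self._chain = [
            self.bn1, self.act1, self.conv_reduce,
            self.bn2, self.act2, self.conv_v,
            self.bn3, self.act3, self.conv_h,
            self.conv_expand,
        ]

    def forward(self, x):
        if x.shape[1] != self.spec.channels:
            raise InvalidInputError(
                f"LAB expects {self.spec.channels} channels, got {x.shape[1]}"
            )
        if x.shape[2] < 3 or x.shape[3] < 3:
            raise InvalidInputError(
                f"spatial size {x.shape[2]}x{x.shape[3]} cannot support the "
                "factorized 3-tap kernels"
            )
        y = x
        for layer in self._chain:
            y = layer(y)
        return x + y

    def backward(self, grad_out):
        g = grad_out
        for layer in reversed(self._chain):
            g = layer.backward(g)
        return g + grad_out


class FFMModule(Module):
    """Feature fusion: spatial attention from low-level features gates
    the 3x3-convolved high-level features, which are then added back,
    batch-normalized and PReLU-activated.
    """

    def __init__(self, spec: FFMSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        cl, ch = spec.low_channels, spec.high_channels
        self.spec = spec
        self.upsample = UpsampleBilinear2x() if spec.upsample_high else None
        self.conv_high = Conv2d(ch, cl, 3, bias=True, rng=rng)
        self.conv_low = Conv2d(cl, cl, 1, rng=rng)
        self.bn_low = BatchNorm2d(cl)
        self.pool = ChannelMean() if spec.channel_pool else None
        self.sigmoid = Sigmoid()
        self.bn_out = BatchNorm2d(cl)
        self.act_out = PReLU(cl)
        self.last_attention: np.ndarray | None = None
        self._cache = None

    def forward(self, low, high):
        if low.shape[1] != self.spec.low_channels:
            raise ShapeError(
                f"low input has {low.shape[1]} channels, expected {self.spec.low_channels}"
            )
        if high.shape[1] != self.spec.high_channels:
            raise ShapeError(
                f"high input has {high.shape[1]} channels, expected {self.spec.high_channels}"
            )
        if self.upsample is not None:
            if high.shape[2] * 2 != low.shape[2] or high.shape[3] * 2 != low.shape[3]:
                raise ShapeError(
                    f"high {high.shape[2:]} must be half of low {low.shape[2:]} "
                    "before 2x upsampling"
                )
            h = self.upsample(high)
        else:
            if high.shape[2:] != low.shape[2:]:
                raise ShapeError(
                    f"high {high.shape[2:]} and low {low.shape[2:]} sizes differ"
                )
            h = high
        hp = self.conv_high(h)
        a_pre = self.bn_low(self.conv_low(low))
        if self.pool is not None:
            a_pre = self.pool(a_pre)
        a = self.sigmoid(a_pre)
        self.last_attention = a
        fused = a * hp + hp
        out = self.act_out(self.bn_out(fused))
        if self.training:
            self._cache = (a, hp)
        return out

    def backward(self, grad_out):
        a, hp = self._cache
        gs = self.bn_out.backward(self.act_out.backward(grad_out))
        ghp = gs * a + gs
        ga = gs * hp
        if self.pool is not None:
            ga = ga.sum(axis=1, keepdims=True)
        ga = self.sigmoid.backward(ga)
        if self.pool is not None:
            ga = self.pool.backward(ga)
        glow = self.conv_low.backward(self.bn_low.backward(ga))
        ghigh = self.conv_high.backward(ghp)
        if self.upsample is not None:
            ghigh = self.upsample.backward(ghigh)
        return glow, ghigh


def _conv_bn_act(cin, cout, k, stride, dilation, rng):
    pad = dilation * (k - 1) // 2
    return Sequential([
        Conv2d(cin, cout, k, stride=stride, dilation=dilation,
               padding=(pad, pad), rng=rng),
        BatchNorm2d(cout),
        PReLU(cout),
    ])


class MVDNet(Module):
    """The full encoder-decoder network."""

    def __init__(self, spec: MVDNetSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        rng = np.random.default_rng(seed)
        c1, c2, c3 = spec.stage_channels
        r1, r2, r3 = spec.dilations
        n, m, l = spec.depths
        fcd = spec.first_conv_dilation
        self.spec = spec

        self.stem = Sequential(
            [_conv_bn_act(3, c1, 3, 2, fcd, rng),
             _conv_bn_act(c1, c1, 3, 1, 1, rng),
             _conv_bn_act(c1, c1, 3, 1, 1, rng)]
        )
        self.block1 = Sequential([LABModule(LABSpec(c1, r1), rng) for _ in range(n)])
        self.ds1 = _conv_bn_act(spec.boundary_channels(0), c2, 3, 2, fcd, rng)
        self.block2 = Sequential([LABModule(LABSpec(c2, r2), rng) for _ in range(m)])
        self.ds2 = _conv_bn_act(spec.boundary_channels(1), c3, 3, 2, fcd, rng)
        self.block3 = Sequential([LABModule(LABSpec(c3, r3), rng) for _ in range(l)])
        self.pool = AvgPool2x2()

        if spec.use_ffm:
            self.ffm1 = FFMModule(
                FFMSpec(c3, spec.boundary_channels(2), False, spec.ffm_channel_pool), rng)
            self.ffm2 = FFMModule(FFMSpec(c2, c3, True, spec.ffm_channel_pool), rng)
            self.ffm3 = FFMModule(FFMSpec(c1, c2, True, spec.ffm_channel_pool), rng)
            cls_in = c1
        else:
            cls_in = c3
        self.classifier = Conv2d(cls_in, spec.num_classes, 1, bias=True, rng=rng)
        self.up = UpsampleBilinear2x()
        self._cache = None

    # -- helpers ------------------------------------------------------
    def _boundary_concat(self, block_in, block_out, pooled_img):
        parts = []
        if self.spec.use_block_concat:
            parts.append(block_in)
        parts.append(block_out)
        if self.spec.use_image_injection:
            parts.append(pooled_img)
        return np.concatenate(parts, axis=1)

    def _boundary_split(self, grad, c):
        """Invert :meth:`_boundary_concat`; image gradients are dropped."""
        g_in = None
        ofs = 0
        if self.spec.use_block_concat:
            g_in = grad[:, :c]
            ofs = c
        g_out = grad[:, ofs: ofs + c]
        return g_in, g_out

    def forward(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != 3:
            raise InvalidInputError(f"expected N x 3 x H x W input, got {x.shape}")
        N, _, H, W = x.shape
        if H % 8 or W % 8:
            raise InvalidInputError(
                f"input spatial size {H}x{W} must be divisible by 8"
            )
        spec = self.spec
        p1 = self.pool(x) if spec.use_image_injection else None
        p2 = self.pool(p1) if spec.use_image_injection else None
        p3 = self.pool(p2) if spec.use_image_injection else None

        f1 = self.stem(x)
        b1 = self.block1(f1)
        f2 = self.ds1(self._boundary_concat(f1, b1, p1))
        b2 = self.block2(f2)
        f3 = self.ds2(self._boundary_concat(f2, b2, p2))
        b3 = self.block3(f3)

        if spec.use_ffm:
            h3 = self._boundary_concat(f3, b3, p3)
            u1 = self.ffm1(f3, h3)
            u2 = self.ffm2(f2, u1)
            u3 = self.ffm3(f1, u2)
            z = self.classifier(u3)
            y = self.up(z)
        else:
            z = self.classifier(b3)
            y = self.up(self.up(self.up(z)))
        return y

    def backward(self, grad_y):
        """Backpropagate through the whole network; gradients accumulate
        on the parameters.  The input-image gradient is not returned."""
        spec = self.spec
        c1, c2, c3 = spec.stage_channels
        if spec.use_ffm:
            gz = self.up.backward(grad_y)
            gu3 = self.classifier.backward(gz)
            glow1, gu2 = self.ffm3.backward(gu3)   # glow1 -> f1
            glow2, gu1 = self.ffm2.backward(gu2)   # glow2 -> f2
            glow3, gh3 = self.ffm1.backward(gu1)   # glow3 -> f3
            g_in3, gb3 = self._boundary_split(gh3, c3)
            gf3 = glow3 + self.block3.backward(gb3)
            if g_in3 is not None:
                gf3 = gf3 + g_in3
        else:
            gz = grad_y
            for _ in range(3):
                gz = self.up.backward(gz)
            gb3 = self.classifier.backward(gz)
            glow1 = glow2 = None
            gf3 = self.block3.backward(gb3)

        gd2 = self.ds2.backward(gf3)
        g_in2, gb2 = self._boundary_split(gd2, c2)
        gf2 = self.block2.backward(gb2)
        if g_in2 is not None:
            gf2 = gf2 + g_in2
        if glow2 is not None:
            gf2 = gf2 + glow2

        gd1 = self.ds1.backward(gf2)
        g_in1, gb1 = self._boundary_split(gd1, c1)
        gf1 = self.block1.backward(gb1)
        if g_in1 is not None:
            gf1 = gf1 + g_in1
        if glow1 is not None:
            gf1 = gf1 + glow1

        self.stem.backward(gf1)

    def attention_maps(self) -> list[np.ndarray]:
        """Attention maps of the three FFMs from the most recent forward."""
        if not self.spec.use_ffm:
            return []
        return [f.last_attention for f in (self.ffm1, self.ffm2, self.ffm3)]


def build_mvdnet(spec: MVDNetSpec | None = None, seed: int = 0) -> MVDNet:
    """Assemble the network from a declarative spec (default: full model)."""
    return MVDNet(spec if spec is not None else MVDNetSpec(), seed=seed)


def mvdnet_forward(network: MVDNet, image: np.ndarray) -> np.ndarray:
    """Run one 3 x H x W image (or an N x 3 x H x W batch) through the
    network and return per-pixel class scores at full input resolution."""
    arr = np.asarray(image, dtype=np.float64)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    out = network(arr)
    return out[0] if squeeze else out


def lab_forward(x: np.ndarray, module: LABModule) -> np.ndarray:
    """Forward a C x H x W (or batched) feature map through one LAB module."""
    arr = np.asarray(x, dtype=np.float64)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    out = module(arr)
    return out[0] if squeeze else out


def ffm_forward(low: np.ndarray, high: np.ndarray, module: FFMModule) -> np.ndarray:
    """Forward (low, high) feature maps (C x H x W or batched) through one FFM."""
    lo, hi = np.asarray(low, dtype=np.float64), np.asarray(high, dtype=np.float64)
    squeeze = lo.ndim == 3
    if squeeze:
        lo, hi = lo[None], hi[None]
    out = module(lo, hi)
    return out[0] if squeeze else out
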