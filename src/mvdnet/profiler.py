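"""Closed-form architecture audit: parameters, FLOPs, shape trace, receptive field.

Everything here is computed from the declarative :class:`MVDNetSpec`
alone - no weight arrays are instantiated - so the audit serves as an
independent oracle against the built network's own parameter
enumeration.

Conventions (also stated in every report):

* parameters: every convolution counts ``kh*kw*C_in*C_out/groups``
  weights plus ``C_out`` bias terms when the conv is not immediately
  followed by a batch norm; BN contributes ``2C`` (scale, shift) and
  PReLU ``C`` (one slope per channel).
* FLOPs: 2 per multiply-accumulate for convolutions; elementwise costs
  of 2/element for BN (inference-time scale and shift) and PReLU,
  4/element for sigmoid, 1/element for additions, multiplications,
  pooling and channel-mean reduction, and 7/element for bilinear
  interpolation outputs.  The paper-independent 2xMAC convention makes
  FLOP figures report-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .arch import FeatureMapSpec, MVDNetSpec
from .errors import InvalidInputError

__all__ = [
    "TraceRow",
    "ProfileReport",
    "count_parameters",
    "parameter_breakdown",
    "count_flops",
    "layer_shape_trace",
    "receptive_field",
    "profile",
    "trace_to_tsv",
]

FLOP_CONVENTION = (
    "2 FLOPs per multiply-accumulate; BN 2/elem, PReLU 2/elem, sigmoid 4/elem, "
    "add/mul/pool 1/elem, bilinear interpolation 7/output elem"
)


# ---------------------------------------------------------------------------
# parameter arithmetic
# ---------------------------------------------------------------------------

def _conv_p(cin, cout, kh, kw, groups=1, bias=False):
    return kh * kw * (cin // groups) * cout + (cout if bias else 0)


def _bn_p(c):
    return 2 * c


def _prelu_p(c):
    return c


def _stem_p(c1):
    one = _conv_p(3, c1, 3, 3) + _bn_p(c1) + _prelu_p(c1)
    rest = _conv_p(c1, c1, 3, 3) + _bn_p(c1) + _prelu_p(c1)
    return one + 2 * rest


def _lab_p(C):
    c = C // 2
    total = _bn_p(C) + _prelu_p(C)
    total += _conv_p(C, c, 1, 1)
    total += _bn_p(c) + _prelu_p(c)
    total += _conv_p(c, c, 3, 1, groups=c)
    total += _bn_p(c) + _prelu_p(c)
    total += _conv_p(c, c, 1, 3, groups=c, bias=True)
    total += _conv_p(c, C, 1, 1, bias=True)
    return total


def _ds_p(cin, cout):
    return _conv_p(cin, cout, 3, 3) + _bn_p(cout) + _prelu_p(cout)


def _ffm_p(cl, ch):
    total = _conv_p(cl, cl, 1, 1) + _bn_p(cl)          # low branch (conv feeds BN)
    total += _conv_p(ch, cl, 3, 3, bias=True)          # high branch
    total += _bn_p(cl) + _prelu_p(cl)                  # post-fusion
    return total


def count_parameters(spec: MVDNetSpec) -> int:
    """Exact trainable-parameter count of the network built from ``spec``."""
    spec.validate()
    c1, c2, c3 = spec.stage_channels
    n, m, l = spec.depths
    total = _stem_p(c1)
    total += n * _lab_p(c1)
    total += _ds_p(spec.boundary_channels(0), c2)
    total += m * _lab_p(c2)
    total += _ds_p(spec.boundary_channels(1), c3)
    total += l * _lab_p(c3)
    if spec.use_ffm:
        total += _ffm_p(c3, spec.boundary_channels(2))
        total += _ffm_p(c2, c3)
        total += _ffm_p(c1, c2)
        cls_in = c1
    else:
        cls_in = c3
    total += _conv_p(cls_in, spec.num_classes, 1, 1, bias=True)
    return total


def parameter_breakdown(spec: MVDNetSpec) -> dict:
    """Parameters split by kind, so either counting convention (with or
    without normalization/activation parameters) can be checked."""
    total = count_parameters(spec)
    c1, c2, c3 = spec.stage_channels
    n, m, l = spec.depths
    # norm+act parameters, mirroring the walk above
    na = 3 * (3 * c1)                                   # stem BN+PReLU
    na += n * (3 * c1 + 2 * 3 * (c1 // 2))              # per-LAB BN+PReLU terms
    na += 3 * c2
    na += m * (3 * c2 + 2 * 3 * (c2 // 2))
    na += 3 * c3
    na += l * (3 * c3 + 2 * 3 * (c3 // 2))
    if spec.use_ffm:
        na += (2 * c3 + 3 * c3) + (2 * c2 + 3 * c2) + (2 * c1 + 3 * c1)
    return {
        "total": total,
        "norm_and_activation": na,
        "convolution": total - na,
    }


# ---------------------------------------------------------------------------
# FLOPs
# ---------------------------------------------------------------------------

def _conv_f(cin, cout, kh, kw, ho, wo, groups=1, bias=False):
    f = 2 * kh * kw * (cin // groups) * cout * ho * wo
    if bias:
        f += cout * ho * wo
    return f


def _bn_f(c, h, w):
    return 2 * c * h * w


def _prelu_f(c, h, w):
    return 2 * c * h * w


def _lab_f(C, h, w):
    c = C // 2
    f = _bn_f(C, h, w) + _prelu_f(C, h, w)
    f += _conv_f(C, c, 1, 1, h, w)
    f += _bn_f(c, h, w) + _prelu_f(c, h, w)
    f += _conv_f(c, c, 3, 1, h, w, groups=c)
    f += _bn_f(c, h, w) + _prelu_f(c, h, w)
    f += _conv_f(c, c, 1, 3, h, w, groups=c, bias=True)
    f += _conv_f(c, C, 1, 1, h, w, bias=True)
    f += C * h * w                                      # residual addition
    return f


def _ffm_f(cl, ch, h, w, upsampled: bool, channel_pool: bool):
    f = 0
    if upsampled:
        f += 7 * ch * h * w                             # bilinear 2x outputs
    f += _conv_f(ch, cl, 3, 3, h, w, bias=True)
    f += _conv_f(cl, cl, 1, 1, h, w) + _bn_f(cl, h, w)
    if channel_pool:
        f += cl * h * w                                 # channel-mean reduction
        f += 4 * h * w                                  # sigmoid on 1 channel
    else:
        f += 4 * cl * h * w
    f += 2 * cl * h * w                                 # gate multiply + add
    f += _bn_f(cl, h, w) + _prelu_f(cl, h, w)
    return f


def count_flops(spec: MVDNetSpec, input_spec: FeatureMapSpec | None = None) -> float:
    """Giga-FLOPs of one forward pass at the given input size."""
    spec.validate()
    inp = input_spec or FeatureMapSpec(3, 512, 512)
    if inp.channels != 3:
        raise InvalidInputError("input must have 3 channels")
    H, W = inp.height, inp.width
    if H % 8 or W % 8:
        raise InvalidInputError(f"input size {H}x{W} must be divisible by 8")
    c1, c2, c3 = spec.stage_channels
    n, m, l = spec.depths
    h1, w1 = H // 2, W // 2
    h2, w2 = H // 4, W // 4
    h3, w3 = H // 8, W // 8
    f = 0
    # stem
    f += _conv_f(3, c1, 3, 3, h1, w1) + _bn_f(c1, h1, w1) + _prelu_f(c1, h1, w1)
    f += 2 * (_conv_f(c1, c1, 3, 3, h1, w1) + _bn_f(c1, h1, w1) + _prelu_f(c1, h1, w1))
    if spec.use_image_injection:
        f += 3 * h1 * w1 + 3 * h2 * w2 + 3 * h3 * w3    # average pooling chain
    f += n * _lab_f(c1, h1, w1)
    f += _conv_f(spec.boundary_channels(0), c2, 3, 3, h2, w2) \
        + _bn_f(c2, h2, w2) + _prelu_f(c2, h2, w2)
    f += m * _lab_f(c2, h2, w2)
    f += _conv_f(spec.boundary_channels(1), c3, 3, 3, h3, w3) \
        + _bn_f(c3, h3, w3) + _prelu_f(c3, h3, w3)
    f += l * _lab_f(c3, h3, w3)
    if spec.use_ffm:
        f += _ffm_f(c3, spec.boundary_channels(2), h3, w3, False, spec.ffm_channel_pool)
        f += _ffm_f(c2, c3, h2, w2, True, spec.ffm_channel_pool)
        f += _ffm_f(c1, c2, h1, w1, True, spec.ffm_channel_pool)
        f += _conv_f(c1, spec.num_classes, 1, 1, h1, w1, bias=True)
        f += 7 * spec.num_classes * H * W               # final bilinear 2x
    else:
        f += _conv_f(c3, spec.num_classes, 1, 1, h3, w3, bias=True)
        f += 7 * spec.num_classes * (h2 * w2 + h1 * w1 + H * W)
    return f / 1e9


# ---------------------------------------------------------------------------
# shape trace
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceRow:
    layer: str
    operator: str
    mode: str
    channels: int
    height: int
    width: int

    @property
    def output_size(self) -> str:
        return f"{self.height}x{self.width}"

    def as_tuple(self):
        return (self.layer, self.operator, self.mode, self.channels, self.output_size)


def _stride2_mode(fcd: int) -> str:
    return "Stride 2" if fcd == 1 else f"Stride 2, Dilated {fcd}"


def layer_shape_trace(spec: MVDNetSpec,
                      input_spec: FeatureMapSpec | None = None) -> list[TraceRow]:
    """One row per architectural element, mirroring the layer-table layout
    (Layer, Operator, Mode, Channel, Output size)."""
    spec.validate()
    inp = input_spec or FeatureMapSpec(3, 512, 512)
    H, W = inp.height, inp.width
    if H % 8 or W % 8:
        raise InvalidInputError(f"input size {H}x{W} must be divisible by 8")
    c1, c2, c3 = spec.stage_channels
    r1, r2, r3 = spec.dilations
    n, m, l = spec.depths
    h1, w1 = H // 2, W // 2
    h2, w2 = H // 4, W // 4
    h3, w3 = H // 8, W // 8
    rows: list[TraceRow] = []
    lid = 1

    def one(operator, mode, ch, h, w):
        nonlocal lid
        rows.append(TraceRow(str(lid), operator, mode, ch, h, w))
        lid += 1

    def block(depth, mode, ch, h, w):
        nonlocal lid
        label = str(lid) if depth == 1 else f"{lid}-{lid + depth - 1}"
        rows.append(TraceRow(label, f"{depth}x LAB module", mode, ch, h, w))
        lid += depth

    one("3x3 Conv", _stride2_mode(spec.first_conv_dilation), c1, h1, w1)
    one("3x3 Conv", "Stride 1", c1, h1, w1)
    one("3x3 Conv", "Stride 1", c1, h1, w1)
    block(n, f"Dilated {r1}", c1, h1, w1)
    one("3x3 Conv", _stride2_mode(spec.first_conv_dilation), c2, h2, w2)
    block(m, f"Dilated {r2}", c2, h2, w2)
    one("3x3 Conv", _stride2_mode(spec.first_conv_dilation), c3, h3, w3)
    block(l, f"Dilated {r3}", c3, h3, w3)
    if spec.use_ffm:
        one("1x FFM module", "-", c3, h3, w3)
        one("1x FFM module", "-", c2, h2, w2)
        one("1x FFM module", "-", c1, h1, w1)
        one("1x1 Conv", "Stride 1", spec.num_classes, h1, w1)
        one("Bilinear interpolation", "x2", spec.num_classes, H, W)
    else:
        one("1x1 Conv", "Stride 1", spec.num_classes, h3, w3)
        one("Bilinear interpolation", "x8", spec.num_classes, H, W)
    return rows


def trace_to_tsv(rows: list[TraceRow]) -> str:
    lines = ["Layer\tOperator\tMode\tChannel\tOutput size"]
    for r in rows:
        lines.append("\t".join(map(str, r.as_tuple())))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# receptive field
# ---------------------------------------------------------------------------

def receptive_field(spec: MVDNetSpec) -> int:
    """Receptive field (pixels, per axis) of the encoder output, by the
    standard recursive accumulation rf += (k_eff - 1) * jump."""
    spec.validate()
    fcd = spec.first_conv_dilation
    rf, jump = 1, 1

    def conv(k_eff, stride):
        nonlocal rf, jump
        rf += (k_eff - 1) * jump
        jump *= stride

    conv(2 * fcd + 1, 2)            # stem conv 1
    conv(3, 1)
    conv(3, 1)
    for stage in range(3):
        r = spec.dilations[stage]
        for _ in range(spec.depths[stage]):
            conv(2 * r + 1, 1)      # the factorized 3x1 / 1x3 pair per axis
        if stage < 2:
            conv(2 * fcd + 1, 2)    # downsampler
    return rf


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class ProfileReport:
    params_exact: int
    params_millions: float
    params_breakdown: dict
    flops_g: float
    input_size: tuple[int, int]
    layer_trace: list[TraceRow] = field(repr=False)
    receptive_field: int = 0
    flop_convention: str = FLOP_CONVENTION

    def to_json(self) -> str:
        d = {
            "params_exact": self.params_exact,
            "params_millions": self.params_millions,
            "params_breakdown": self.params_breakdown,
            "flops_g": self.flops_g,
            "input_size": list(self.input_size),
            "receptive_field": self.receptive_field,
            "flop_convention": self.flop_convention,
            "layer_trace": [r.as_tuple() for r in self.layer_trace],
        }
        return json.dumps(d, indent=2)

    def to_tsv(self) -> str:
        return trace_to_tsv(self.layer_trace)


def profile(spec: MVDNetSpec, input_spec: FeatureMapSpec | None = None) -> ProfileReport:
    inp = input_spec or FeatureMapSpec(3, 512, 512)
    params = count_parameters(spec)
    return ProfileReport(
        params_exact=params,
        params_millions=round(params / 1e6, 2),
        params_breakdown=parameter_breakdown(spec),
        flops_g=count_flops(spec, inp),
        input_size=(inp.height, inp.width),
        layer_trace=layer_shape_trace(spec, inp),
        receptive_field=receptive_field(spec),
    )
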