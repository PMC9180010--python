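"""Profiler audits: closed-form parameter counts against the built
network, FLOP scaling laws, shape traces, receptive fields."""

import itertools

import numpy as np
import pytest

from mvdnet import (
    FeatureMapSpec,
    MVDNetSpec,
    build_mvdnet,
    count_flops,
    count_parameters,
    layer_shape_trace,
    profile,
    receptive_field,
)
from mvdnet.errors import InvalidInputError
from mvdnet.profiler import _conv_f, _lab_f, parameter_breakdown, trace_to_tsv

TABLE_DEPTHS = [(2, 2, 2), (2, 2, 4), (2, 4, 4), (4, 4, 4), (2, 8, 8)]


@pytest.mark.parametrize("depths", TABLE_DEPTHS)
def test_closed_form_matches_built_network(depths):
    spec = MVDNetSpec(depths=depths)
    assert count_parameters(spec) == build_mvdnet(spec).num_parameters()


@pytest.mark.parametrize("overrides", [
    {"use_ffm": False},
    {"use_block_concat": False},
    {"use_image_injection": False},
    {"use_ffm": False, "use_block_concat": False, "use_image_injection": False},
    {"ffm_channel_pool": False},
    {"num_classes": 4, "stage_channels": (8, 12, 24)},
])
def test_closed_form_matches_built_network_across_toggles(overrides):
    spec = MVDNetSpec(**overrides)
    assert count_parameters(spec) == build_mvdnet(spec).num_parameters()


def test_default_model_audits_to_072_million():
    report = profile(MVDNetSpec())
    assert report.params_millions == 0.72
    assert report.params_exact == build_mvdnet(MVDNetSpec()).num_parameters()


def test_breakdown_sums_to_total():
    b = parameter_breakdown(MVDNetSpec())
    assert b["convolution"] + b["norm_and_activation"] == b["total"]


def test_parameters_and_flops_monotone_in_depth():
    """The depth-ablation ordering: params and FLOPs never decrease as
    any of n, m, l grows."""
    params = [count_parameters(MVDNetSpec(depths=d)) for d in TABLE_DEPTHS]
    flops = [count_flops(MVDNetSpec(depths=d)) for d in TABLE_DEPTHS]
    assert params == sorted(params)
    assert flops == sorted(flops)
    for bump in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
        base = MVDNetSpec()
        grown = MVDNetSpec(depths=tuple(d + b for d, b in zip(base.depths, bump)))
        assert count_parameters(grown) >= count_parameters(base)
        assert count_flops(grown) >= count_flops(base)


def test_dilation_never_changes_parameter_count():
    """All three dilation variants carry identical parameters."""
    full = count_parameters(MVDNetSpec())
    assert count_parameters(MVDNetSpec(dilations=(1, 1, 1))) == full
    assert count_parameters(MVDNetSpec(first_conv_dilation=2)) == full


def test_flop_closed_forms():
    # one 1x1 conv, 16->16, on 8x8, no bias: 2 * 16 * 16 * 64 MAC-pairs
    assert _conv_f(16, 16, 1, 1, 8, 8) == 32768
    # doubling both spatial dims quadruples FLOPs, parameters unchanged
    spec = MVDNetSpec()
    f1 = count_flops(spec, FeatureMapSpec(3, 512, 512))
    f2 = count_flops(spec, FeatureMapSpec(3, 1024, 1024))
    assert f2 == pytest.approx(4 * f1)
    assert count_parameters(spec) == count_parameters(spec)


def test_flops_compose_over_depth():
    """Growing (2,4,4) to (2,8,8) adds exactly four stage-2 and four
    stage-3 module costs at their respective map sizes."""
    inp = FeatureMapSpec(3, 512, 512)
    delta = count_flops(MVDNetSpec(depths=(2, 8, 8)), inp) \
        - count_flops(MVDNetSpec(depths=(2, 4, 4)), inp)
    expected = (4 * _lab_f(64, 128, 128) + 4 * _lab_f(128, 64, 64)) / 1e9
    assert delta == pytest.approx(expected)


def test_flops_reject_bad_input():
    with pytest.raises(InvalidInputError):
        count_flops(MVDNetSpec(), FeatureMapSpec(3, 100, 96))


def test_trace_row_count_and_anchor_rows():
    rows = layer_shape_trace(MVDNetSpec())
    assert len(rows) == 13
    assert rows[0].as_tuple() == ("1", "3x3 Conv", "Stride 2", 32, "256x256")
    ffm1 = rows[8]
    assert (ffm1.operator, ffm1.channels, ffm1.output_size) == ("1x FFM module", 128, "64x64")


def test_trace_at_native_resolution_restores_size():
    rows = layer_shape_trace(MVDNetSpec(), FeatureMapSpec(3, 576, 768))
    assert (rows[-1].height, rows[-1].width) == (576, 768)
    assert rows[0].output_size == "288x384"


def test_trace_without_ffm_is_classifier_plus_upsampling():
    rows = layer_shape_trace(MVDNetSpec(use_ffm=False))
    ops = [r.operator for r in rows]
    assert "1x FFM module" not in ops
    assert ops[-2:] == ["1x1 Conv", "Bilinear interpolation"]
    assert rows[-1].mode == "x8"


def test_trace_tsv_has_table_column_order():
    text = trace_to_tsv(layer_shape_trace(MVDNetSpec()))
    assert text.splitlines()[0] == "Layer\tOperator\tMode\tChannel\tOutput size"


def test_receptive_field_accumulation():
    """Independent recursive fold over the encoder path agrees with the
    profiler, and dilation strictly enlarges the field."""
    def oracle(spec):
        rf, jump = 1, 1
        seq = [(2 * spec.first_conv_dilation + 1, 2), (3, 1), (3, 1)]
        for stage in range(3):
            seq += [(2 * spec.dilations[stage] + 1, 1)] * spec.depths[stage]
            if stage < 2:
                seq.append((2 * spec.first_conv_dilation + 1, 2))
        for k, s in seq:
            rf += (k - 1) * jump
            jump *= s
        return rf

    for spec in (MVDNetSpec(), MVDNetSpec(dilations=(1, 1, 1)),
                 MVDNetSpec(depths=(1, 1, 1))):
        assert receptive_field(spec) == oracle(spec)
    assert receptive_field(MVDNetSpec()) > receptive_field(MVDNetSpec(dilations=(1, 1, 1)))
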