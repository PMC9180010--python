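"""Confusion matrix, IoU/mIoU and stratified reports against
brute-force set-arithmetic oracles."""

import numpy as np
import pytest

from mvdnet import (
    ConfusionMatrix,
    LabelSchema,
    SceneSample,
    accumulate_confusion,
    iou_and_miou,
    stratified_report,
)
from mvdnet.errors import InvalidInputError
from mvdnet.metrics import report_to_tsv


def brute_force_miou(pred, ref, num_classes, include_background=True):
    """Independent oracle: per-class set arithmetic on boolean masks."""
    ious = []
    for c in range(num_classes):
        if not include_background and c == 0:
            continue
        p = pred == c
        r = ref == c
        union = (p | r).sum()
        if union == 0:
            continue
        ious.append((p & r).sum() / union)
    return float(np.mean(ious))


def test_perfect_prediction_scores_one():
    ref = np.random.default_rng(0).integers(0, 10, size=(16, 16))
    cm = ConfusionMatrix(10).add(ref, ref)
    report = iou_and_miou(cm)
    assert report.miou == 1.0
    assert all(v in (None, 1.0) for v in report.per_class_iou.values())


def test_printed_grid_iou_is_six_tenths():
    """A 4x4 grid with 6 true positives, 2 false positives and 2 false
    negatives for class 1 gives IoU 6/10."""
    ref = np.array([[1, 1, 1, 1], [1, 1, 1, 1], [0, 0, 0, 0], [0, 0, 0, 0]])
    pred = np.array([[1, 1, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 0, 0]])
    cm = ConfusionMatrix(2).add(pred, ref)
    report = iou_and_miou(cm)
    assert report.per_class_iou["1"] == pytest.approx(0.6)


def test_disjoint_class_scores_zero():
    ref = np.zeros((4, 4), dtype=int)
    ref[:2] = 1
    pred = np.zeros((4, 4), dtype=int)
    pred[2:] = 1
    report = iou_and_miou(ConfusionMatrix(3).add(pred, ref))
    assert report.per_class_iou["1"] == 0.0
    assert report.per_class_iou["2"] is None   # never referenced nor predicted


def test_empty_union_classes_excluded_from_mean():
    ref = np.zeros((4, 4), dtype=int)
    pred = np.zeros((4, 4), dtype=int)
    report = iou_and_miou(ConfusionMatrix(10).add(pred, ref))
    assert report.miou == 1.0
    assert sum(v is not None for v in report.per_class_iou.values()) == 1


def test_confusion_accumulation_is_additive():
    rng = np.random.default_rng(1)
    pred = rng.integers(0, 5, size=(8, 8))
    ref = rng.integers(0, 5, size=(8, 8))
    whole = ConfusionMatrix(5).add(pred, ref)
    halves = ConfusionMatrix(5)
    accumulate_confusion(halves, pred[:4], ref[:4])
    accumulate_confusion(halves, pred[4:], ref[4:])
    np.testing.assert_array_equal(whole.counts, halves.counts)
    assert halves.total == 64


def test_identical_inputs_grow_only_diagonal():
    ref = np.random.default_rng(2).integers(0, 4, size=(6, 6))
    cm = ConfusionMatrix(4).add(ref, ref)
    off = cm.counts - np.diag(np.diag(cm.counts))
    assert off.sum() == 0


def test_shape_and_range_validation():
    cm = ConfusionMatrix(4)
    with pytest.raises(InvalidInputError):
        cm.add(np.zeros((2, 2), dtype=int), np.zeros((3, 3), dtype=int))
    with pytest.raises(InvalidInputError):
        cm.add(np.full((2, 2), 7), np.zeros((2, 2), dtype=int))
    with pytest.raises(InvalidInputError):
        iou_and_miou(ConfusionMatrix(4))


@pytest.mark.parametrize("include_background", [True, False])
def test_miou_matches_brute_force_oracle(include_background):
    rng = np.random.default_rng(3)
    for _ in range(100):
        pred = rng.integers(0, 10, size=(8, 8))
        ref = rng.integers(0, 10, size=(8, 8))
        cm = ConfusionMatrix(10).add(pred, ref)
        got = iou_and_miou(cm, include_background=include_background).miou
        want = brute_force_miou(pred, ref, 10, include_background)
        assert got == pytest.approx(want, abs=1e-12)


def _make_samples():
    rng = np.random.default_rng(4)
    samples, preds = [], []
    for age in ("40-50", "40-50", "60-70"):
        mask = rng.integers(0, 10, size=(8, 8))
        pred = rng.integers(0, 10, size=(8, 8))
        samples.append(SceneSample(image=np.zeros((8, 8, 3)), mask=mask,
                                   age_group=age, gender="female"))
        preds.append(pred)
    return samples, preds


def test_single_stratum_equals_global_report():
    samples, preds = _make_samples()
    report = stratified_report(samples, preds, "gender")
    assert list(report.group_reports) == ["female"]
    assert report.group_reports["female"].miou == pytest.approx(report.miou)


def test_stratified_matches_hand_built_matrices():
    samples, preds = _make_samples()
    report = stratified_report(samples, preds, "age_group")
    cm_young = ConfusionMatrix(10)
    cm_young.add(preds[0], samples[0].mask).add(preds[1], samples[1].mask)
    assert report.group_reports["40-50"].miou == pytest.approx(
        iou_and_miou(cm_young).miou)
    cm_old = ConfusionMatrix(10).add(preds[2], samples[2].mask)
    assert report.group_reports["60-70"].miou == pytest.approx(
        iou_and_miou(cm_old).miou)


def test_age_strata_emitted_in_canonical_order():
    rng = np.random.default_rng(5)
    samples, preds = [], []
    for age in ("60-70", "40-50", "50-60"):
        mask = rng.integers(0, 10, size=(4, 4))
        samples.append(SceneSample(image=np.zeros((4, 4, 3)), mask=mask, age_group=age))
        preds.append(mask)
    report = stratified_report(samples, preds, "age_group")
    assert list(report.group_reports) == ["40-50", "50-60", "60-70"]


def test_missing_metadata_key_rejected():
    samples, preds = _make_samples()
    with pytest.raises(InvalidInputError):
        stratified_report(samples, preds, "hospital")


def test_tsv_report_column_order():
    samples, preds = _make_samples()
    schema = LabelSchema.default()
    report = stratified_report(samples, preds, "age_group", schema=schema)
    lines = report_to_tsv(report, "age_group").splitlines()
    assert lines[0].split("\t")[:4] == ["age_group", "mIoU (%)", "cn5", "cn7"]
    assert lines[0].split("\t")[-1] == "pv"
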