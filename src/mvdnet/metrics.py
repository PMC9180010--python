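"""Confusion-matrix accumulation, per-class IoU, mIoU and stratified reports.

All IoU statistics derive from a single pixel-count confusion matrix
(rows = reference class, columns = predicted class):

    IoU_c = cm[c,c] / (row_c + col_c - cm[c,c])

Classes whose union is empty (never referenced and never predicted) are
excluded from the mean.  The mean can include or exclude the background
class; both conventions are exposed because stratified accuracy tables
in this domain list only foreground columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import AGE_GROUPS, GENDERS, LabelSchema
from .errors import InvalidInputError

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "accumulate_confusion",
    "iou_and_miou",
    "stratified_report",
    "report_to_tsv",
    "TABLE_COLUMN_ORDER",
]

#: foreground column order of the stratified accuracy tables
TABLE_COLUMN_ORDER = ("cn5", "cn7", "cn9", "cn10", "aica+cn7", "pica+cn7",
                      "pica", "aica", "pv")


class ConfusionMatrix:
    """Pixel-count accumulator over ``num_classes`` classes."""

    def __init__(self, num_classes: int = 10):
        self.num_classes = num_classes
        self.counts = np.zeros((num_classes, num_classes), dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def add(self, prediction: np.ndarray, reference: np.ndarray) -> "ConfusionMatrix":
        pred = np.asarray(prediction)
        ref = np.asarray(reference)
        if pred.shape != ref.shape:
            raise InvalidInputError(
                f"prediction {pred.shape} and reference {ref.shape} shapes differ"
            )
        k = self.num_classes
        for name, arr in (("prediction", pred), ("reference", ref)):
            if arr.min() < 0 or arr.max() >= k:
                raise InvalidInputError(f"{name} contains labels outside [0, {k})")
        idx = ref.reshape(-1) * k + pred.reshape(-1)
        self.counts += np.bincount(idx, minlength=k * k).reshape(k, k)
        return self

    def merged(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        out = ConfusionMatrix(self.num_classes)
        out.counts = self.counts + other.counts
        return out


def accumulate_confusion(cm: ConfusionMatrix, prediction: np.ndarray,
                         reference: np.ndarray) -> ConfusionMatrix:
    """Increment ``cm`` with one prediction/reference pair (in place)."""
    return cm.add(prediction, reference)


@dataclass
class EvalReport:
    """Per-class IoU (None where the union is empty), their mean, and
    optional per-stratum sub-reports."""

    per_class_iou: dict
    miou: float
    pixel_count: int = 0
    include_background: bool = True
    group_reports: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "miou": self.miou,
            "per_class_iou": self.per_class_iou,
            "pixel_count": self.pixel_count,
            "include_background": self.include_background,
        }
        if self.group_reports:
            d["groups"] = {k: v.to_dict() for k, v in self.group_reports.items()}
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def iou_and_miou(cm: ConfusionMatrix, include_background: bool = True,
                 schema: LabelSchema | None = None) -> EvalReport:
    """Compute per-class IoU and their arithmetic mean from ``cm``."""
    if cm.total == 0:
        raise InvalidInputError("confusion matrix is empty")
    counts = cm.counts
    diag = np.diag(counts).astype(np.float64)
    union = counts.sum(axis=0) + counts.sum(axis=1) - diag
    names = (schema.abbreviations if schema is not None
             else [str(i) for i in range(cm.num_classes)])
    per_class: dict = {}
    included = []
    for c in range(cm.num_classes):
        if union[c] == 0:
            per_class[names[c]] = None
            continue
        iou = float(diag[c] / union[c])
        per_class[names[c]] = iou
        if include_background or c != 0:
            included.append(iou)
    if not included:
        raise InvalidInputError("no class has a nonempty union")
    return EvalReport(
        per_class_iou=per_class,
        miou=float(np.mean(included)),
        pixel_count=cm.total,
        include_background=include_background,
    )


def _stratum_order(values: set) -> list:
    for canonical in (AGE_GROUPS, GENDERS):
        if values <= set(canonical):
            return [v for v in canonical if v in values]
    return sorted(values)


def stratified_report(samples, predictions, key: str, num_classes: int = 10,
                      include_background: bool = True,
                      schema: LabelSchema | None = None) -> EvalReport:
    """Global report plus one sub-report per value of metadata ``key``
    (e.g. ``age_group`` or ``gender``), emitted in canonical order."""
    if len(samples) != len(predictions):
        raise InvalidInputError("need one prediction per sample")
    global_cm = ConfusionMatrix(num_classes)
    strata: dict[str, ConfusionMatrix] = {}
    for sample, pred in zip(samples, predictions):
        if not hasattr(sample, key):
            raise InvalidInputError(f"sample {sample.sample_id!r} lacks metadata {key!r}")
        value = getattr(sample, key)
        global_cm.add(pred, sample.mask)
        strata.setdefault(value, ConfusionMatrix(num_classes)).add(pred, sample.mask)
    report = iou_and_miou(global_cm, include_background, schema)
    for value in _stratum_order(set(strata)):
        report.group_reports[value] = iou_and_miou(
            strata[value], include_background, schema)
    return report


def report_to_tsv(report: EvalReport, group_label: str = "group") -> str:
    """Render a report (with strata) in the stratified-table column order:
    mIoU (%) first, then the nine foreground classes."""
    header = [group_label, "mIoU (%)"] + list(TABLE_COLUMN_ORDER)
    lines = ["\t".join(header)]

    def fmt(r: EvalReport, label: str) -> str:
        cells = [label, f"{100 * r.miou:.2f}"]
        for name in TABLE_COLUMN_ORDER:
            v = r.per_class_iou.get(name)
            cells.append("-" if v is None else f"{100 * v:.2f}")
        return "\t".join(cells)

    lines.append(fmt(report, "all"))
    for label, sub in report.group_reports.items():
        lines.append(fmt(sub, label))
    return "\n".join(lines) + "\n"
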