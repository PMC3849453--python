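"""Diagnostic-accuracy metrics for verdicts against a reference labelling.

The reference may come from human review or from simulation ground truth.
"appropriate" is the positive class by default, so PPV reads as "accuracy on
prescriptions called appropriate" and NPV as "accuracy on prescriptions
called inappropriate".  References marked ``unknown`` (e.g. reviewers who
were unsure) are excluded from every denominator and counted separately.
Wilson score intervals accompany each defined proportion.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from statsmodels.stats.proportion import proportion_confint

from .classify import AopVerdict
from .records import _open_maybe

__all__ = [
    "LabelledVerdict",
    "MetricsReport",
    "evaluate",
    "join_labels",
    "read_labels",
    "write_labels",
    "write_report",
]

CLASSES = ("appropriate", "inappropriate")
REFERENCE_CLASSES = CLASSES + ("unknown",)


@dataclass(frozen=True)
class LabelledVerdict:
    rx_id: str
    predicted: str  # appropriate | inappropriate
    reference: str  # appropriate | inappropriate | unknown

    def __post_init__(self) -> None:
        if self.predicted not in CLASSES:
            raise ValueError(f"bad predicted class: {self.predicted!r}")
        if self.reference not in REFERENCE_CLASSES:
            raise ValueError(f"bad reference class: {self.reference!r}")


@dataclass
class MetricsReport:
    """Confusion counts and the derived proportions.

    A metric whose denominator is empty is ``None`` (undefined), never 0.
    ``cis`` maps each defined metric to its Wilson score interval.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    n_unknown: int
    positive_class: str = "appropriate"
    ci_method: str = "wilson"
    cis: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_known(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        out = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
            "n_unknown": self.n_unknown, "positive_class": self.positive_class,
            "ci_method": self.ci_method,
        }
        for name, (lo, hi) in self.cis.items():
            out[f"{name}_ci_low"], out[f"{name}_ci_high"] = lo, hi
        return out


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def evaluate(
    pairs: Iterable[LabelledVerdict],
    positive_class: str = "appropriate",
    ci_alpha: float = 0.05,
) -> MetricsReport:
    """Compute sensitivity, specificity, PPV and NPV for a labelled batch.

    With the default positive class, sensitivity = TP/(TP+FN) is the
    fraction of reference-appropriate prescriptions the model also calls
    appropriate, and so on.  Swapping ``positive_class`` swaps
    (sensitivity, specificity) and (PPV, NPV).
    """
    if positive_class not in CLASSES:
        raise ValueError(f"bad positive class: {positive_class!r}")
    tp = fp = fn = tn = unknown = 0
    for pair in pairs:
        if pair.reference == "unknown":
            unknown += 1
            continue
        pred_pos = pair.predicted == positive_class
        ref_pos = pair.reference == positive_class
        if pred_pos and ref_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif ref_pos:
            fn += 1
        else:
            tn += 1
    report = MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        n_unknown=unknown,
        positive_class=positive_class,
    )
    for name, num, den in (
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ):
        if den:
            lo, hi = proportion_confint(num, den, alpha=ci_alpha, method="wilson")
            report.cis[name] = (float(lo), float(hi))
    return report


def join_labels(
    verdicts: Iterable[AopVerdict], labels: Mapping[str, str]
) -> list[LabelledVerdict]:
    """Pair each verdict with its reference label.

    A verdict whose rx_id has no label is an error: silently dropping
    records would bias every metric.
    """
    out = []
    for v in verdicts:
        if v.rx_id not in labels:
            raise KeyError(f"no reference label for {v.rx_id}")
        predicted = "appropriate" if v.appropriate else "inappropriate"
        out.append(LabelledVerdict(v.rx_id, predicted, labels[v.rx_id]))
    return out


def read_labels(source) -> dict[str, str]:
    """Read a label file: rx_id <TAB> reference (extra columns ignored)."""
    stream, needs_close = _open_maybe(source, "r")
    try:
        rows = list(csv.reader(stream, delimiter="\t"))
    finally:
        if needs_close:
            stream.close()
    labels: dict[str, str] = {}
    for row in rows[1:] if rows and rows[0][:1] == ["rx_id"] else rows:
        if not row:
            continue
        if len(row) < 2 or row[1] not in REFERENCE_CLASSES:
            raise ValueError(f"malformed label row: {row!r}")
        labels[row[0]] = row[1]
    return labels


def write_labels(labels: Mapping[str, str], sink) -> None:
    stream, needs_close = _open_maybe(sink, "w")
    try:
        stream.write("rx_id\treference\n")
        for rx_id, ref in labels.items():
            stream.write(f"{rx_id}\t{ref}\n")
    finally:
        if needs_close:
            stream.close()


def write_report(report: MetricsReport, sink) -> None:
    """Write the report as two-column key/value delimited text."""
    stream, needs_close = _open_maybe(sink, "w")
    try:
        for key, value in report.as_dict().items():
            stream.write(f"{key}\t{'' if value is None else value}\n")
    finally:
        if needs_close:
            stream.close()
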