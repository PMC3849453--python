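"""Appropriateness-of-a-prescription (AOP) rule engine.

A prescription with diagnoses D and medications M is judged against a mined
:class:`~aopmine.mining.KnowledgeBase`.  A DM or MM pair occurring in the
prescription is *positive* when its stored Q exceeds the knowledge base's
cut-off (strictly) and, if the significance filter is enabled, its one-sided
Fisher p-value is below alpha; pairs absent from the knowledge base —
including those removed by the support filter — are never positive.

Strict mode requires all three rules:

1. the number of positive DM pairs plus positive MM pairs is at least the
   number of medications m;
2. every diagnosis takes part in at least one positive DM pair;
3. every medication takes part in at least one positive DM or MM pair.

Lenient mode calls a prescription appropriate as soon as it has at least one
positive DM pair; it is provided for comparison with the strict conjunction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

from .mining import KnowledgeBase
from .records import PrescriptionRecord, _open_maybe

__all__ = [
    "AopVerdict",
    "BatchSummary",
    "positive_pairs",
    "classify",
    "classify_batch",
    "write_verdicts",
    "read_verdicts",
]

MODES = ("strict", "lenient")


@dataclass(frozen=True)
class AopVerdict:
    """Per-prescription decision with a per-rule audit trail.

    ``offending_diagnoses`` lists the diagnoses with no positive DM pair
    (rule 2 failures); ``offending_medications`` the medications covered by
    neither a positive DM nor a positive MM pair (rule 3 failures).  All
    lists are sorted so re-runs are bit-identical.
    """

    rx_id: str
    appropriate: bool
    rule1_pass: bool
    rule2_pass: bool
    rule3_pass: bool
    positive_dm: tuple[tuple[str, str], ...]
    positive_mm: tuple[tuple[str, str], ...]
    offending_diagnoses: tuple[str, ...]
    offending_medications: tuple[str, ...]


@dataclass(frozen=True)
class BatchSummary:
    n_total: int
    n_appropriate: int
    n_inappropriate: int

    @property
    def fraction_appropriate(self) -> float:
        return self.n_appropriate / self.n_total if self.n_total else 0.0

    @property
    def fraction_inappropriate(self) -> float:
        return self.n_inappropriate / self.n_total if self.n_total else 0.0


def positive_pairs(
    rx: PrescriptionRecord, kb: KnowledgeBase
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Positive DM and MM pairs occurring within ``rx``, in sorted order."""
    pos_dm = [
        (d, m)
        for d in sorted(rx.diagnoses)
        for m in sorted(rx.medications)
        if kb.is_positive_dm(d, m)
    ]
    meds = sorted(rx.medications)
    pos_mm = [
        (meds[i], meds[j])
        for i in range(len(meds))
        for j in range(i + 1, len(meds))
        if kb.is_positive_mm(meds[i], meds[j])
    ]
    return pos_dm, pos_mm


def classify(
    rx: PrescriptionRecord, kb: KnowledgeBase, mode: str = "strict"
) -> AopVerdict:
    """Apply the three AOP rules (or the lenient single-rule variant) to ``rx``.

    The verdict is a pure function of the record, the knowledge base and its
    stored thresholds.  The rule flags are always reported, even in lenient
    mode, so the audit trail stays comparable across modes.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode: {mode!r} (expected one of {MODES})")
    pos_dm, pos_mm = positive_pairs(rx, kb)
    m = rx.n_medications

    rule1 = len(pos_dm) + len(pos_mm) >= m
    covered_dx = {d for d, _ in pos_dm}
    offending_dx = tuple(d for d in sorted(rx.diagnoses) if d not in covered_dx)
    rule2 = not offending_dx
    covered_med = {med for _, med in pos_dm}
    for m1, m2 in pos_mm:
        covered_med.add(m1)
        covered_med.add(m2)
    offending_med = tuple(x for x in sorted(rx.medications) if x not in covered_med)
    rule3 = not offending_med

    if mode == "lenient":
        appropriate = len(pos_dm) > 0
    else:
        appropriate = rule1 and rule2 and rule3
    return AopVerdict(
        rx_id=rx.rx_id,
        appropriate=appropriate,
        rule1_pass=rule1,
        rule2_pass=rule2,
        rule3_pass=rule3,
        positive_dm=tuple(pos_dm),
        positive_mm=tuple(pos_mm),
        offending_diagnoses=offending_dx,
        offending_medications=offending_med,
    )


def classify_batch(
    records: Iterable[PrescriptionRecord], kb: KnowledgeBase, mode: str = "strict"
) -> tuple[list[AopVerdict], BatchSummary]:
    verdicts = [classify(rx, kb, mode=mode) for rx in records]
    n_app = sum(v.appropriate for v in verdicts)
    return verdicts, BatchSummary(len(verdicts), n_app, len(verdicts) - n_app)


_VERDICT_HEADER = (
    "rx_id",
    "appropriate",
    "rule1_pass",
    "rule2_pass",
    "rule3_pass",
    "positive_dm",
    "positive_mm",
    "offending_diagnoses",
    "offending_medications",
)


def _pack_pairs(pairs: Sequence[tuple[str, str]]) -> str:
    return ";".join(f"{x}|{y}" for x, y in pairs)


def _unpack_pairs(cell: str) -> tuple[tuple[str, str], ...]:
    if cell == "":
        return ()
    return tuple(tuple(p.split("|", 1)) for p in cell.split(";"))  # type: ignore[return-value]


def write_verdicts(verdicts: Iterable[AopVerdict], sink) -> None:
    """One row per prescription: flags plus packed audit lists."""
    stream, needs_close = _open_maybe(sink, "w")
    try:
        w = csv.writer(stream, delimiter="\t", lineterminator="\n")
        w.writerow(_VERDICT_HEADER)
        for v in verdicts:
            w.writerow(
                [
                    v.rx_id,
                    int(v.appropriate),
                    int(v.rule1_pass),
                    int(v.rule2_pass),
                    int(v.rule3_pass),
                    _pack_pairs(v.positive_dm),
                    _pack_pairs(v.positive_mm),
                    ";".join(v.offending_diagnoses),
                    ";".join(v.offending_medications),
                ]
            )
    finally:
        if needs_close:
            stream.close()


def read_verdicts(source) -> list[AopVerdict]:
    stream, needs_close = _open_maybe(source, "r")
    try:
        rows = list(csv.reader(stream, delimiter="\t"))
    finally:
        if needs_close:
            stream.close()
    if not rows or tuple(rows[0]) != _VERDICT_HEADER:
        raise ValueError("not a verdict file (missing or wrong header)")
    out = []
    for row in rows[1:]:
        out.append(
            AopVerdict(
                rx_id=row[0],
                appropriate=bool(int(row[1])),
                rule1_pass=bool(int(row[2])),
                rule2_pass=bool(int(row[3])),
                rule3_pass=bool(int(row[4])),
                positive_dm=_unpack_pairs(row[5]),
                positive_mm=_unpack_pairs(row[6]),
                offending_diagnoses=tuple(row[7].split(";")) if row[7] else (),
                offending_medications=tuple(row[8].split(";")) if row[8] else (),
            )
        )
    return out
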