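"""Prescription data model, tabular claims I/O, and record-level cleaning.

A claims extract is modelled as a stream of prescriptions, each carrying an
identifier, a short list of diagnosis codes (ICD9-CM style) and a list of
medication codes (ATC style).  Cleaning is record-level: a prescription with
any missing/invalid code, any code in an excluded category, or an
out-of-bounds code count is dropped wholly, and every dropped record is
attributed to exactly one reason in the :class:`CleaningReport`.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "PrescriptionRecord",
    "Vocabulary",
    "CleaningReport",
    "read_prescriptions",
    "write_prescriptions",
    "load_mapping",
    "DEFAULT_DIAGNOSIS_PATTERN",
    "DEFAULT_MEDICATION_PATTERN",
]

#: Approximates ICD9-CM codes: a leading digit/E/V then 2-4 digits ("401", "E8500").
DEFAULT_DIAGNOSIS_PATTERN = r"^[0-9EV][0-9]{2,4}$"
#: Approximates a full (level-5) ATC code such as "A10AB01".
DEFAULT_MEDICATION_PATTERN = r"^[A-Z][0-9]{2}[A-Z]{2}[0-9]{2}$"

HEADER = ("rx_id", "diagnoses", "medications")


@dataclass(frozen=True)
class PrescriptionRecord:
    """One prescription: the unit over which co-occurrence is defined.

    ``diagnoses`` and ``medications`` are stored as tuples that behave as
    ordered sets: ingestion deduplicates while preserving first-seen order.
    """

    rx_id: str
    diagnoses: tuple[str, ...]
    medications: tuple[str, ...]

    @property
    def n_diagnoses(self) -> int:
        return len(self.diagnoses)

    @property
    def n_medications(self) -> int:
        return len(self.medications)


@dataclass
class Vocabulary:
    """Validity and exclusion rules for one code system.

    A code is *valid* iff it matches ``validity_pattern`` and starts with no
    exclusion prefix.  ``mapping``, when given, is applied before validation;
    a code absent from the mapping invalidates the whole record.
    """

    kind: str  # "diagnosis" | "medication"
    validity_pattern: str = ""
    exclusion_prefixes: tuple[str, ...] = ()
    mapping: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("diagnosis", "medication"):
            raise ValueError(f"unknown vocabulary kind: {self.kind!r}")
        if not self.validity_pattern:
            self.validity_pattern = (
                DEFAULT_DIAGNOSIS_PATTERN
                if self.kind == "diagnosis"
                else DEFAULT_MEDICATION_PATTERN
            )
        self.exclusion_prefixes = tuple(self.exclusion_prefixes)
        self._regex = re.compile(self.validity_pattern)

    @classmethod
    def diagnosis(cls, **kwargs) -> "Vocabulary":
        return cls(kind="diagnosis", **kwargs)

    @classmethod
    def medication(cls, **kwargs) -> "Vocabulary":
        return cls(kind="medication", **kwargs)

    def map_code(self, code: str) -> str | None:
        """Translate ``code``; ``None`` marks an unmapped (hence invalid) code."""
        if self.mapping is None:
            return code
        return self.mapping.get(code)

    def is_wellformed(self, code: str) -> bool:
        return bool(self._regex.match(code))

    def is_excluded(self, code: str) -> bool:
        return any(code.startswith(p) for p in self.exclusion_prefixes)


@dataclass
class CleaningReport:
    """Partition of the input rows by cleaning outcome.

    Every input row lands in exactly one bucket, so
    ``n_input == n_kept + n_dropped_invalid_code + n_dropped_excluded_category
    + n_dropped_cardinality`` always holds.  Malformed rows (wrong column
    count) are counted as invalid, never silently skipped.
    """

    n_input: int = 0
    n_kept: int = 0
    n_dropped_invalid_code: int = 0
    n_dropped_excluded_category: int = 0
    n_dropped_cardinality: int = 0

    @property
    def n_dropped(self) -> int:
        return (
            self.n_dropped_invalid_code
            + self.n_dropped_excluded_category
            + self.n_dropped_cardinality
        )

    def check(self) -> None:
        if self.n_input != self.n_kept + self.n_dropped:
            raise AssertionError("cleaning report buckets do not partition the input")


def _dedup(codes: Iterable[str]) -> tuple[str, ...]:
    return tuple(dict.fromkeys(codes))


def _parse_codes(cell: str, list_delim: str) -> list[str]:
    if cell == "":
        return []
    return [c.strip() for c in cell.split(list_delim)]


def _open_maybe(source, mode: str):
    """Return (stream, needs_close) for a path or an already-open text stream."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode, encoding="utf-8", newline=""), True


def read_prescriptions(
    source,
    dx_vocab: Vocabulary | None = None,
    med_vocab: Vocabulary | None = None,
    *,
    field_delim: str = "\t",
    list_delim: str = ";",
    min_dx: int = 1,
    max_dx: int = 3,
    min_meds: int = 1,
    max_meds: int = 15,
) -> tuple[list[PrescriptionRecord], CleaningReport]:
    """Read a delimited claims file and apply the record-level cleaning filters.

    The first row must be a header.  Each subsequent row carries
    ``rx_id``, a ``list_delim``-packed diagnosis list and a medication list.
    Filters are applied in a fixed order per record, and the first failing
    filter claims the record for its report bucket:

    1. structural problems, unmapped/missing/ill-formed codes → invalid;
    2. any code in an excluded category (prefix match) → excluded;
    3. code counts outside ``[min_dx, max_dx]`` / ``[min_meds, max_meds]``
       (after deduplication) → cardinality.

    Returns the kept records in input order plus the :class:`CleaningReport`.
    """
    dx_vocab = dx_vocab or Vocabulary.diagnosis()
    med_vocab = med_vocab or Vocabulary.medication()
    stream, needs_close = _open_maybe(source, "r")
    report = CleaningReport()
    kept: list[PrescriptionRecord] = []
    try:
        reader = csv.reader(stream, delimiter=field_delim)
        try:
            next(reader)  # header
        except StopIteration as exc:
            raise ValueError("empty stream: no header row") from exc
        for row in reader:
            report.n_input += 1
            outcome = _clean_row(
                row, dx_vocab, med_vocab, list_delim,
                min_dx, max_dx, min_meds, max_meds,
            )
            if isinstance(outcome, PrescriptionRecord):
                report.n_kept += 1
                kept.append(outcome)
            elif outcome == "invalid":
                report.n_dropped_invalid_code += 1
            elif outcome == "excluded":
                report.n_dropped_excluded_category += 1
            else:
                report.n_dropped_cardinality += 1
    finally:
        if needs_close:
            stream.close()
    report.check()
    return kept, report


def _clean_row(
    row: Sequence[str],
    dx_vocab: Vocabulary,
    med_vocab: Vocabulary,
    list_delim: str,
    min_dx: int,
    max_dx: int,
    min_meds: int,
    max_meds: int,
):
    if len(row) != 3 or row[0] == "":
        return "invalid"
    rx_id = row[0]
    lists: list[tuple[str, ...]] = []
    for cell, vocab in ((row[1], dx_vocab), (row[2], med_vocab)):
        codes = _parse_codes(cell, list_delim)
        if not codes:
            return "invalid"  # missing codes
        mapped = []
        for code in codes:
            code = vocab.map_code(code)
            if code is None or not vocab.is_wellformed(code):
                return "invalid"
            mapped.append(code)
        lists.append(_dedup(mapped))
    diagnoses, medications = lists
    if any(dx_vocab.is_excluded(c) for c in diagnoses) or any(
        med_vocab.is_excluded(c) for c in medications
    ):
        return "excluded"
    if not (min_dx <= len(diagnoses) <= max_dx):
        return "cardinality"
    if not (min_meds <= len(medications) <= max_meds):
        return "cardinality"
    return PrescriptionRecord(rx_id, diagnoses, medications)


def write_prescriptions(
    records: Iterable[PrescriptionRecord],
    sink,
    *,
    field_delim: str = "\t",
    list_delim: str = ";",
) -> None:
    """Write records in the same delimited layout :func:`read_prescriptions` reads.

    Round-trip property: reading back a written file reproduces the records
    (and the bytes, on a second serialization) exactly.
    """
    stream, needs_close = _open_maybe(sink, "w")
    try:
        writer = csv.writer(stream, delimiter=field_delim, lineterminator="\n")
        writer.writerow(HEADER)
        for rec in records:
            writer.writerow(
                [rec.rx_id, list_delim.join(rec.diagnoses), list_delim.join(rec.medications)]
            )
    finally:
        if needs_close:
            stream.close()


def load_mapping(source, *, field_delim: str = "\t") -> dict[str, str]:
    """Load a two-column code→code translation table."""
    stream, needs_close = _open_maybe(source, "r")
    try:
        mapping: dict[str, str] = {}
        for row in csv.reader(stream, delimiter=field_delim):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise ValueError(f"mapping rows need exactly 2 columns, got {row!r}")
            mapping[row[0]] = row[1]
        return mapping
    finally:
        if needs_close:
            stream.close()
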