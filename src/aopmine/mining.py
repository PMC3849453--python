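"""Pairwise association mining over prescription records.

Co-occurrence is defined at prescription level: a disease and a medication
(a DM pair), or two medications (an MM pair), co-occur if they appear in the
same prescription.  Each pair's strength Q is computed from its 2x2
contingency table over the corpus, either as the lift

    Q = P(X, Y) / (P(X) P(Y)) = a * N / ((a + b) * (a + c))

or as the relative risk P(Y | X) / P(Y | not X).  Q = 1 means no
association, Q > 1 a positive one, Q < 1 a negative one.  Pairs with fewer
than ``min_support`` co-occurrences are treated as uncommon-or-rare and kept
out of the knowledge base; optionally a one-sided Fisher exact test prunes
associations whose excess co-occurrence is not significant.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from scipy.stats import fisher_exact

from .records import PrescriptionRecord

__all__ = [
    "ContingencyTable",
    "AssociationEntry",
    "KnowledgeBase",
    "PairCounts",
    "QUndefinedError",
    "count_pairs",
    "build_table",
    "compute_q",
    "fisher_p",
    "build_knowledge_base",
    "save_kb",
    "load_kb",
]

Q_MODES = ("lift", "relative_risk")
ALTERNATIVES = ("greater", "two_sided")


class QUndefinedError(ValueError):
    """Raised when a table's margins leave Q with a zero denominator."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 co-occurrence table for one item pair over the corpus.

    ``a`` prescriptions contain both items, ``b`` only X, ``c`` only Y and
    ``d`` neither; ``n`` is the corpus size a+b+c+d.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError(f"negative cell in contingency table: {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationEntry:
    """A scored DM or MM pair.

    For MM pairs ``item_x`` is the lexicographically smaller medication code
    (MM pairs are unordered).  For DM pairs ``item_x`` is the diagnosis and
    ``item_y`` the medication.  ``p_value`` is the one-sided (greater)
    Fisher exact p, present only when the knowledge base was built with the
    significance filter enabled.
    """

    pair_kind: str  # "DM" | "MM"
    item_x: str
    item_y: str
    cooccurrence: int
    q: float
    p_value: float | None = None


class PairCounts(NamedTuple):
    """Raw co-occurrence counts plus per-item marginals over a corpus."""

    dm: Counter
    mm: Counter
    dx_marginals: Counter
    med_marginals: Counter
    n_prescriptions: int


def count_pairs(records: Iterable[PrescriptionRecord]) -> PairCounts:
    """Count DM and MM pair co-occurrences, one count per prescription.

    Marginals count the prescriptions containing each item (codes are
    already unique within a record).  MM pairs are canonicalized so that
    ``item_x < item_y``.  An empty corpus is an error: N = 0 leaves every Q
    undefined.
    """
    dm: Counter = Counter()
    mm: Counter = Counter()
    dx_marg: Counter = Counter()
    med_marg: Counter = Counter()
    n = 0
    for rec in records:
        n += 1
        meds = rec.medications
        dx_marg.update(rec.diagnoses)
        med_marg.update(meds)
        for d in rec.diagnoses:
            for m in meds:
                dm[(d, m)] += 1
        for i in range(len(meds)):
            for j in range(i + 1, len(meds)):
                mm[mm_key(meds[i], meds[j])] += 1
    if n == 0:
        raise ValueError("empty corpus: no prescriptions to count")
    return PairCounts(dm, mm, dx_marg, med_marg, n)


def mm_key(m1: str, m2: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered medication pair."""
    return (m1, m2) if m1 < m2 else (m2, m1)


def build_table(
    pair_count: int, marginal_x: int, marginal_y: int, n_total: int,
    pair: tuple[str, str] | None = None,
) -> ContingencyTable:
    """Assemble the 2x2 table from a pair count, the item marginals and N."""
    if not (0 <= pair_count <= min(marginal_x, marginal_y) <= max(marginal_x, marginal_y) <= n_total):
        raise ValueError(
            f"inconsistent counts for pair {pair or '?'}: "
            f"a={pair_count}, |X|={marginal_x}, |Y|={marginal_y}, N={n_total}"
        )
    a = pair_count
    b = marginal_x - a
    c = marginal_y - a
    d = n_total - a - b - c
    return ContingencyTable(a, b, c, d)


def compute_q(table: ContingencyTable, mode: str = "lift") -> float:
    """Association strength Q of the pair behind ``table``.

    ``lift`` is a*N/((a+b)(a+c)); it is symmetric in the two items and
    invariant to scaling all four cells.  ``relative_risk`` is
    (a/(a+b)) / (c/(c+d)) and equals +inf when a > 0 but c = 0.  A zero
    denominator (an item never observed, or an empty row) raises
    :class:`QUndefinedError`.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n == 0:
        raise QUndefinedError("empty table: N = 0")
    if mode == "lift":
        mx, my = a + b, a + c
        if mx == 0 or my == 0:
            raise QUndefinedError("zero marginal: lift undefined")
        return a * n / (mx * my)
    if mode == "relative_risk":
        if a + b == 0 or c + d == 0:
            raise QUndefinedError("empty row: relative risk undefined")
        p1 = a / (a + b)
        p2 = c / (c + d)
        if p2 == 0.0:
            if p1 == 0.0:
                raise QUndefinedError("item Y never observed: relative risk undefined")
            return math.inf
        return p1 / p2
    raise ValueError(f"unknown q mode: {mode!r} (expected one of {Q_MODES})")


def fisher_p(table: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher exact p-value of the table (hypergeometric tail probability).

    ``greater`` tests for excess co-occurrence (the direction relevant for
    pruning spuriously positive associations); ``two_sided`` is the usual
    two-tailed test.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"unknown alternative: {alternative!r}")
    alt = "two-sided" if alternative == "two_sided" else "greater"
    return float(
        fisher_exact([[table.a, table.b], [table.c, table.d]], alternative=alt)[1]
    )


@dataclass
class KnowledgeBase:
    """The mined DM/MM association lookup plus the thresholds it was built with.

    ``dm`` maps (diagnosis, medication) and ``mm`` maps the canonical
    (smaller, larger) medication pair to an :class:`AssociationEntry`.  Every
    stored entry has ``cooccurrence >= min_support``.  The thresholds are
    stored so a classification run is reproducible from the file alone.
    Absent pairs are non-positive by construction: that is exactly how
    uncommon-or-rare combinations trigger inappropriateness downstream.
    """

    dm: dict[tuple[str, str], AssociationEntry] = field(default_factory=dict)
    mm: dict[tuple[str, str], AssociationEntry] = field(default_factory=dict)
    n_prescriptions: int = 0
    min_support: int = 5
    q_mode: str = "lift"
    q_threshold: float = 1.0
    fisher_alpha: float | None = None

    def get_dm(self, diagnosis: str, medication: str) -> AssociationEntry | None:
        return self.dm.get((diagnosis, medication))

    def get_mm(self, med1: str, med2: str) -> AssociationEntry | None:
        return self.mm.get(mm_key(med1, med2))

    def _is_positive(self, entry: AssociationEntry | None) -> bool:
        if entry is None:
            return False
        if not entry.q > self.q_threshold:  # boundary Q == threshold is NOT positive
            return False
        if self.fisher_alpha is not None:
            return entry.p_value is not None and entry.p_value < self.fisher_alpha
        return True

    def is_positive_dm(self, diagnosis: str, medication: str) -> bool:
        return self._is_positive(self.get_dm(diagnosis, medication))

    def is_positive_mm(self, med1: str, med2: str) -> bool:
        return self._is_positive(self.get_mm(med1, med2))

    @property
    def n_entries(self) -> int:
        return len(self.dm) + len(self.mm)


def build_knowledge_base(
    records: Iterable[PrescriptionRecord],
    *,
    min_support: int = 5,
    q_mode: str = "lift",
    q_threshold: float = 1.0,
    fisher_alpha: float | None = None,
) -> KnowledgeBase:
    """Mine a corpus into a :class:`KnowledgeBase`.

    Keeps exactly the DM and MM pairs with at least ``min_support``
    co-occurrences (the raw count ``a``, not a frequency), scores each with
    Q in ``q_mode``, and — when ``fisher_alpha`` is set — attaches the
    one-sided Fisher p-value used by the positivity check.  Pairs whose Q is
    undefined are skipped.
    """
    if q_mode not in Q_MODES:
        raise ValueError(f"unknown q mode: {q_mode!r}")
    counts = count_pairs(records)
    kb = KnowledgeBase(
        n_prescriptions=counts.n_prescriptions,
        min_support=min_support,
        q_mode=q_mode,
        q_threshold=q_threshold,
        fisher_alpha=fisher_alpha,
    )
    specs = (
        ("DM", counts.dm, counts.dx_marginals, counts.med_marginals, kb.dm),
        ("MM", counts.mm, counts.med_marginals, counts.med_marginals, kb.mm),
    )
    for kind, pair_counter, marg_x, marg_y, store in specs:
        for (x, y), a in pair_counter.items():
            if a < min_support:
                continue
            table = build_table(a, marg_x[x], marg_y[y], counts.n_prescriptions, pair=(x, y))
            try:
                q = compute_q(table, mode=q_mode)
            except QUndefinedError:
                continue
            p = fisher_p(table, "greater") if fisher_alpha is not None else None
            store[(x, y)] = AssociationEntry(kind, x, y, a, q, p)
    return kb


_KB_MAGIC = "#aopmine-kb\t1"
_KB_HEADER_FIELDS = ("n_prescriptions", "min_support", "q_mode", "q_threshold", "fisher_alpha")
_KB_COLUMNS = "kind\titem_x\titem_y\tcooccurrence\tq\tp_value"


class KBFormatError(ValueError):
    """Raised on a malformed or incomplete knowledge-base file."""


def save_kb(kb: KnowledgeBase, sink) -> None:
    """Serialize a knowledge base as delimited text with a header block.

    Floats are written with ``repr`` so the round trip is bit-exact.
    """
    from .records import _open_maybe

    stream, needs_close = _open_maybe(sink, "w")
    try:
        stream.write(_KB_MAGIC + "\n")
        stream.write(f"#n_prescriptions\t{kb.n_prescriptions}\n")
        stream.write(f"#min_support\t{kb.min_support}\n")
        stream.write(f"#q_mode\t{kb.q_mode}\n")
        stream.write(f"#q_threshold\t{kb.q_threshold!r}\n")
        alpha = "none" if kb.fisher_alpha is None else repr(kb.fisher_alpha)
        stream.write(f"#fisher_alpha\t{alpha}\n")
        stream.write(_KB_COLUMNS + "\n")
        for store in (kb.dm, kb.mm):
            for key in sorted(store):
                e = store[key]
                p = "" if e.p_value is None else repr(e.p_value)
                stream.write(
                    f"{e.pair_kind}\t{e.item_x}\t{e.item_y}\t{e.cooccurrence}\t{e.q!r}\t{p}\n"
                )
    finally:
        if needs_close:
            stream.close()


def load_kb(source) -> KnowledgeBase:
    """Load a knowledge base written by :func:`save_kb`.

    A missing or unrecognized header field is a fatal format error: without
    the thresholds the classification rules are not reproducible.
    """
    from .records import _open_maybe

    stream, needs_close = _open_maybe(source, "r")
    try:
        lines = iter(stream.read().splitlines())
    finally:
        if needs_close:
            stream.close()
    first = next(lines, None)
    if first != _KB_MAGIC:
        raise KBFormatError(f"not a knowledge-base file (bad magic line: {first!r})")
    header: dict[str, str] = {}
    columns = None
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].partition("\t")
            header[key] = value
        else:
            columns = line
            break
    missing = [f for f in _KB_HEADER_FIELDS if f not in header]
    if missing:
        raise KBFormatError(f"knowledge-base header missing fields: {missing}")
    if columns != _KB_COLUMNS:
        raise KBFormatError(f"unexpected column line: {columns!r}")
    alpha_raw = header["fisher_alpha"]
    kb = KnowledgeBase(
        n_prescriptions=int(header["n_prescriptions"]),
        min_support=int(header["min_support"]),
        q_mode=header["q_mode"],
        q_threshold=float(header["q_threshold"]),
        fisher_alpha=None if alpha_raw == "none" else float(alpha_raw),
    )
    if kb.q_mode not in Q_MODES:
        raise KBFormatError(f"unknown q_mode in file: {kb.q_mode!r}")
    for line in lines:
        parts = line.split("\t")
        if len(parts) != 6:
            raise KBFormatError(f"malformed entry row: {line!r}")
        kind, x, y, a, q, p = parts
        entry = AssociationEntry(
            kind, x, y, int(a), float(q), None if p == "" else float(p)
        )
        if kind == "DM":
            kb.dm[(x, y)] = entry
        elif kind == "MM":
            kb.mm[(x, y)] = entry
        else:
            raise KBFormatError(f"unknown pair kind: {kind!r}")
    return kb
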