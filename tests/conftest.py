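import random

import pytest

from aopmine import (
    AssociationEntry,
    KnowledgeBase,
    PrescriptionRecord,
)


@pytest.fixture
def toy_records() -> list[PrescriptionRecord]:
    return [
        PrescriptionRecord("rx1", ("401",), ("C03AA01", "C07AB02")),
        PrescriptionRecord("rx2", ("401", "250"), ("C03AA01", "A10BA02")),
        PrescriptionRecord("rx3", ("250",), ("A10BA02",)),
    ]


def make_kb(dm=(), mm=(), q_threshold=1.0, fisher_alpha=None, min_support=5):
    """Assemble a KnowledgeBase directly from (x, y, q[, p]) tuples."""
    kb = KnowledgeBase(
        n_prescriptions=1000,
        min_support=min_support,
        q_mode="lift",
        q_threshold=q_threshold,
        fisher_alpha=fisher_alpha,
    )
    for spec in dm:
        x, y, q = spec[:3]
        p = spec[3] if len(spec) > 3 else None
        kb.dm[(x, y)] = AssociationEntry("DM", x, y, min_support, q, p)
    for spec in mm:
        x, y, q = spec[:3]
        p = spec[3] if len(spec) > 3 else None
        key = (x, y) if x < y else (y, x)
        kb.mm[key] = AssociationEntry("MM", key[0], key[1], min_support, q, p)
    return kb


def random_corpus(rng: random.Random, n_records: int, n_dx: int = 6, n_meds: int = 10):
    """Small random corpus used by brute-force counting oracles."""
    dx_codes = [str(400 + i) for i in range(n_dx)]
    med_codes = [f"{chr(65 + i)}01AA01" for i in range(n_meds)]
    records = []
    for i in range(n_records):
        dxs = rng.sample(dx_codes, rng.randint(1, 3))
        meds = rng.sample(med_codes, rng.randint(1, min(6, n_meds)))
        records.append(PrescriptionRecord(f"rx{i}", tuple(dxs), tuple(meds)))
    return records
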