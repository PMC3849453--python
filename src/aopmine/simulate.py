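"""Synthetic prescription-claims generator with known association structure.

The generator emulates the structure of an outpatient claims extract — one
to three diagnoses and one to fifteen medications per prescription, skewed
disease frequencies, comorbidity-induced confounded associations — and
injects a small fraction of "error" prescriptions in which one medication is
replaced by one that is indicated for none of the recorded diseases.  The
ground truth labels exactly those records inappropriate, which makes the
whole mine→classify→evaluate pipeline testable without external data.

Generative model, per prescription:

1. each disease d is independently present with probability ``prevalence[d]``;
   then each comorbidity link (d_a, d_b, excess) adds d_b with probability
   ``excess`` when d_a is present and d_b is not;  the diagnosis vector is
   redrawn until its count lies in [1, max_dx] (rejection, so the record
   distribution is the exact conditional law);
2. given the diseases, each medication is present independently with
   probability 1 - (1 - background) * prod over present indicating diseases
   of (1 - indication prob); redrawn until the count lies in [1, max_meds];
3. with probability ``error_rate`` a uniformly chosen medication of the
   record is replaced by one drawn uniformly from the medications indicated
   for none of the present diseases (and not already present).

:func:`expected_lift` evaluates the lift a pair would have under steps 1-2
by exact enumeration, the oracle used to validate mined Q values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import PrescriptionRecord

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulationError",
    "simulate",
    "expected_lift",
    "make_config",
    "disease_code",
    "medication_code",
]


class SimulationError(RuntimeError):
    """Raised when a configuration cannot produce the requested corpus."""


def disease_code(i: int) -> str:
    """ICD9-CM-styled synthetic diagnosis code ("401", "402", ...)."""
    if not 0 <= i < 900:
        raise ValueError("disease index out of range 0..899")
    return str(100 + i)


def medication_code(i: int) -> str:
    """ATC-styled synthetic medication code ("A00AA01", "B00AA01", ...)."""
    if not 0 <= i < 2600:
        raise ValueError("medication index out of range 0..2599")
    return f"{chr(65 + i % 26)}{i // 26:02d}AA01"


@dataclass
class SimConfig:
    """Full description of one synthetic corpus.

    ``disease_prevalence`` maps each diagnosis code to its per-prescription
    base probability; ``indication_map`` maps a diagnosis to the medications
    prescribed for it, each with its conditional prescribing probability;
    ``comorbidity_pairs`` lists (disease_a, disease_b, excess probability)
    links; ``background_med_rate`` is the per-medication probability of an
    incidental, disease-independent prescription; ``error_rate`` the
    per-record probability of an injected error.  A single seeded stream
    drives all sampling, so a corpus is fully reproducible from the config.
    """

    n_prescriptions: int
    disease_prevalence: dict[str, float]
    medications: list[str]
    indication_map: dict[str, list[tuple[str, float]]]
    comorbidity_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    background_med_rate: float = 0.0002
    error_rate: float = 0.0
    max_dx: int = 3
    max_meds: int = 15
    seed: int = 0

    def validate(self) -> None:
        if self.n_prescriptions <= 0:
            raise ValueError("n_prescriptions must be positive")
        if not self.disease_prevalence:
            raise ValueError("need at least one disease")
        if not self.medications:
            raise ValueError("need at least one medication")
        med_set = set(self.medications)
        for d, p in self.disease_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {d} outside [0, 1]: {p}")
        for d in self.disease_prevalence:
            inds = self.indication_map.get(d, [])
            if not inds:
                raise ValueError(f"disease {d} has no indicated medication")
            for m, p in inds:
                if m not in med_set:
                    raise ValueError(f"indicated medication {m} not in universe")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"indication probability outside [0, 1]: {p}")
        for a, b, e in self.comorbidity_pairs:
            if a not in self.disease_prevalence or b not in self.disease_prevalence:
                raise ValueError(f"comorbidity pair ({a}, {b}) references unknown disease")
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"comorbidity excess outside [0, 1]: {e}")
        if not 0.0 <= self.background_med_rate <= 1.0:
            raise ValueError("background_med_rate outside [0, 1]")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.error_rate > 0 and all(
            {m for m, _ in self.indication_map.get(d, [])} == med_set
            for d in self.disease_prevalence
        ):
            raise SimulationError(
                "every medication is indicated for every disease: "
                "no candidate exists for error injection"
            )
        if self.max_dx < 1 or self.max_meds < 1:
            raise ValueError("cardinality bounds must be at least 1")

    # -- plain-dict (YAML-friendly) round trip ---------------------------------

    def to_dict(self) -> dict:
        return {
            "n_prescriptions": self.n_prescriptions,
            "disease_prevalence": dict(self.disease_prevalence),
            "medications": list(self.medications),
            "indication_map": {
                d: [[m, p] for m, p in lst] for d, lst in self.indication_map.items()
            },
            "comorbidity_pairs": [[a, b, e] for a, b, e in self.comorbidity_pairs],
            "background_med_rate": self.background_med_rate,
            "error_rate": self.error_rate,
            "max_dx": self.max_dx,
            "max_meds": self.max_meds,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        data = dict(data)
        data["indication_map"] = {
            d: [(m, float(p)) for m, p in lst]
            for d, lst in data.get("indication_map", {}).items()
        }
        data["comorbidity_pairs"] = [
            (a, b, float(e)) for a, b, e in data.get("comorbidity_pairs", [])
        ]
        return cls(**data)


@dataclass
class GroundTruth:
    """Reference labels for a simulated corpus.

    A record is inappropriate iff at least one of its medications was
    injected as an error; ``error_medications`` holds those medications for
    exactly the inappropriate records.
    """

    labels: dict[str, str]
    error_medications: dict[str, list[str]]

    def label(self, rx_id: str) -> str:
        return self.labels[rx_id]

    def errors_for(self, rx_id: str) -> list[str]:
        return self.error_medications.get(rx_id, [])

    @property
    def n_inappropriate(self) -> int:
        return len(self.error_medications)


def _index_config(config: SimConfig):
    dx_codes = list(config.disease_prevalence)
    med_codes = list(config.medications)
    dx_index = {d: i for i, d in enumerate(dx_codes)}
    med_index = {m: i for i, m in enumerate(med_codes)}
    prev = np.array([config.disease_prevalence[d] for d in dx_codes])
    ind = np.zeros((len(dx_codes), len(med_codes)))
    for d, lst in config.indication_map.items():
        for m, p in lst:
            ind[dx_index[d], med_index[m]] = p
    como = [
        (dx_index[a], dx_index[b], e) for a, b, e in config.comorbidity_pairs
    ]
    return dx_codes, med_codes, prev, ind, como


_MAX_REJECTION_ROUNDS = 1000


def simulate(config: SimConfig) -> tuple[list[PrescriptionRecord], GroundTruth]:
    """Draw a corpus and its ground truth from ``config``.

    Deterministic given ``config.seed``; two calls with identical configs
    yield identical corpora.  With ``error_rate == 0`` every record is
    labelled appropriate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dx_codes, med_codes, prev, ind, como = _index_config(config)
    n, n_dis, n_med = config.n_prescriptions, len(dx_codes), len(med_codes)

    # diagnoses: Bernoulli + comorbidity, rejected until count in [1, max_dx]
    dx = np.zeros((n, n_dis), dtype=bool)
    pending = np.arange(n)
    rounds = 0
    while pending.size:
        rounds += 1
        if rounds > _MAX_REJECTION_ROUNDS:
            raise SimulationError(
                "diagnosis sampling failed to satisfy the cardinality bounds; "
                "prevalences and max_dx are incompatible"
            )
        base = rng.random((pending.size, n_dis)) < prev
        for ia, ib, e in como:
            trigger = base[:, ia] & ~base[:, ib]
            hit = rng.random(int(trigger.sum())) < e
            idx = np.nonzero(trigger)[0][hit]
            base[idx, ib] = True
        counts = base.sum(axis=1)
        ok = (counts >= 1) & (counts <= config.max_dx)
        dx[pending[ok]] = base[ok]
        pending = pending[~ok]

    # medications: independent given diseases, rejected until count in [1, max_meds]
    log1m_ind = np.log1p(-np.clip(ind, 0.0, 1.0 - 1e-12))
    meds = np.zeros((n, n_med), dtype=bool)
    pending = np.arange(n)
    rounds = 0
    while pending.size:
        rounds += 1
        if rounds > _MAX_REJECTION_ROUNDS:
            raise SimulationError(
                "medication sampling failed to satisfy the cardinality bounds; "
                "indication probabilities and max_meds are incompatible"
            )
        p_med = 1.0 - (1.0 - config.background_med_rate) * np.exp(
            dx[pending].astype(np.float64) @ log1m_ind
        )
        draw = rng.random((pending.size, n_med)) < p_med
        counts = draw.sum(axis=1)
        ok = (counts >= 1) & (counts <= config.max_meds)
        meds[pending[ok]] = draw[ok]
        pending = pending[~ok]

    rx_ids = [f"rx{i:07d}" for i in range(n)]
    indicated_any = ind > 0
    error_meds: dict[str, list[str]] = {}
    error_rows = np.nonzero(rng.random(n) < config.error_rate)[0]
    for i in error_rows:
        present_dx = np.nonzero(dx[i])[0]
        allowed = ~indicated_any[present_dx].any(axis=0) & ~meds[i]
        candidates = np.nonzero(allowed)[0]
        if candidates.size == 0:
            raise SimulationError(
                f"no error candidate for record {rx_ids[i]}: every medication is "
                "indicated for (or already present with) its diseases"
            )
        present_meds = np.nonzero(meds[i])[0]
        victim = present_meds[rng.integers(present_meds.size)]
        replacement = candidates[rng.integers(candidates.size)]
        meds[i, victim] = False
        meds[i, replacement] = True
        error_meds[rx_ids[i]] = [med_codes[replacement]]

    dx_lists: list[list[str]] = [[] for _ in range(n)]
    for r, c in zip(*np.nonzero(dx)):
        dx_lists[r].append(dx_codes[c])
    med_lists: list[list[str]] = [[] for _ in range(n)]
    for r, c in zip(*np.nonzero(meds)):
        med_lists[r].append(med_codes[c])
    records = [
        PrescriptionRecord(rx_ids[i], tuple(dx_lists[i]), tuple(med_lists[i]))
        for i in range(n)
    ]
    labels = {
        rid: ("inappropriate" if rid in error_meds else "appropriate")
        for rid in rx_ids
    }
    return records, GroundTruth(labels, error_meds)


# ---------------------------------------------------------------------------
# Analytic oracle
# ---------------------------------------------------------------------------

_ENUM_LIMIT = 18  # 2**18 base vectors is the most the exact oracle will walk


def _disease_law(config: SimConfig) -> dict[tuple[bool, ...], float]:
    """Exact law of the final diagnosis vector, conditioned on 1 <= count <= max_dx."""
    dx_codes, _, prev, _, como = _index_config(config)
    n_dis = len(dx_codes)
    if n_dis > _ENUM_LIMIT:
        raise ValueError(
            f"exact enumeration supports at most {_ENUM_LIMIT} diseases, got {n_dis}"
        )
    law: dict[tuple[bool, ...], float] = {}
    for base in itertools.product((False, True), repeat=n_dis):
        p_base = 1.0
        for j, present in enumerate(base):
            p_base *= prev[j] if present else 1.0 - prev[j]
        if p_base == 0.0:
            continue
        # branch on each comorbidity coin, in listed order
        states = [(list(base), p_base)]
        for ia, ib, e in como:
            nxt = []
            for vec, p in states:
                if vec[ia] and not vec[ib]:
                    if e > 0.0:
                        hit = vec.copy()
                        hit[ib] = True
                        nxt.append((hit, p * e))
                    if e < 1.0:
                        nxt.append((vec, p * (1.0 - e)))
                else:
                    nxt.append((vec, p))
            states = nxt
        for vec, p in states:
            key = tuple(vec)
            law[key] = law.get(key, 0.0) + p
    kept = {
        vec: p for vec, p in law.items() if 1 <= sum(vec) <= config.max_dx
    }
    z = sum(kept.values())
    if z == 0.0:
        raise ValueError("diagnosis cardinality bounds have probability zero")
    return {vec: p / z for vec, p in kept.items()}


def _med_presence_probs(config: SimConfig, vec: Sequence[bool], ind: np.ndarray) -> np.ndarray:
    """Per-medication presence probability given a diagnosis vector."""
    present_rows = [j for j, flag in enumerate(vec) if flag]
    absent = np.full(ind.shape[1], 1.0 - config.background_med_rate)
    if present_rows:
        absent *= np.prod(1.0 - ind[present_rows, :], axis=0)
    return 1.0 - absent


def _count_at_most(probs: np.ndarray, kmax: int) -> float:
    """P(sum of independent Bernoullis <= kmax), truncated DP."""
    dist = np.zeros(kmax + 2)
    dist[0] = 1.0
    for p in probs:
        overflow = dist[kmax + 1] + dist[kmax] * p
        dist[1 : kmax + 1] = dist[1 : kmax + 1] * (1.0 - p) + dist[:kmax] * p
        dist[0] *= 1.0 - p
        dist[kmax + 1] = overflow
    return float(dist[: kmax + 1].sum())


def expected_lift(config: SimConfig, disease: str, medication: str) -> float:
    """Analytic lift P(D, M) / (P(D) P(M)) implied by the generative process.

    Computed by exact enumeration of the diagnosis law (including the
    [1, max_dx] conditioning) and exact handling of the [1, max_meds]
    medication conditioning; the error-injection step is not modelled, so
    the value describes the pre-error association structure (exact whenever
    ``error_rate == 0``).  Undefined marginals raise ``ValueError``.
    """
    config.validate()
    dx_codes, med_codes, _, ind, _ = _index_config(config)
    if disease not in config.disease_prevalence:
        raise ValueError(f"unknown disease: {disease}")
    if medication not in config.medications:
        raise ValueError(f"unknown medication: {medication}")
    d_idx = dx_codes.index(disease)
    m_idx = med_codes.index(medication)

    law = _disease_law(config)
    p_d = 0.0
    p_m = 0.0
    p_dm = 0.0
    for vec, p_vec in law.items():
        q = _med_presence_probs(config, vec, ind)
        rest = np.delete(q, m_idx)
        # conditioning event C: 1 <= med count <= max_meds
        p_c = _count_at_most(q, config.max_meds) - float(np.prod(1.0 - q))
        if p_c <= 0.0:
            continue
        # M present guarantees count >= 1; the rest may add up to max_meds - 1
        p_m_and_c = q[m_idx] * _count_at_most(rest, config.max_meds - 1)
        p_m_given = p_m_and_c / p_c
        p_m += p_vec * p_m_given
        if vec[d_idx]:
            p_d += p_vec
            p_dm += p_vec * p_m_given
    if p_d == 0.0 or p_m == 0.0:
        raise ValueError(
            f"zero marginal for ({disease}, {medication}): lift undefined"
        )
    return p_dm / (p_d * p_m)


# ---------------------------------------------------------------------------
# Default corpus structure
# ---------------------------------------------------------------------------

def make_config(
    n_prescriptions: int = 100_000,
    *,
    n_diseases: int = 60,
    n_medications: int = 240,
    meds_per_disease: int = 3,
    indication_probs: Sequence[float] = (0.8, 0.85, 0.9),
    prevalence_total: float = 1.3,
    n_comorbidity_pairs: int = 3,
    comorbidity_excess: float = 0.3,
    background_med_rate: float = 0.0002,
    error_rate: float = 0.05,
    max_dx: int = 3,
    max_meds: int = 15,
    seed: int = 0,
) -> SimConfig:
    """Build the package's default "strong structure" corpus configuration.

    Disease prevalences follow a Zipf (1/rank) profile scaled so the
    expected diagnosis count before conditioning is ``prevalence_total``;
    each disease indicates a disjoint block of ``meds_per_disease``
    medications with high probabilities; the remaining medications are
    reachable only through the incidental background rate or error
    injection; a handful of comorbidity links among mid-prevalence diseases
    reproduce confounded (indirect) associations.
    """
    if n_diseases * meds_per_disease > n_medications:
        raise ValueError("medication universe too small for the indication blocks")
    weights = np.array([1.0 / (i + 1) for i in range(n_diseases)])
    prev = np.minimum(weights / weights.sum() * prevalence_total, 0.95)
    diseases = {disease_code(i): float(prev[i]) for i in range(n_diseases)}
    medications = [medication_code(i) for i in range(n_medications)]
    indication_map = {
        disease_code(i): [
            (
                medication_code(i * meds_per_disease + k),
                float(indication_probs[k % len(indication_probs)]),
            )
            for k in range(meds_per_disease)
        ]
        for i in range(n_diseases)
    }
    comorbidity_pairs = []
    for k in range(n_comorbidity_pairs):
        ia, ib = 10 + 2 * k, 11 + 2 * k
        if ib < n_diseases:
            comorbidity_pairs.append(
                (disease_code(ia), disease_code(ib), comorbidity_excess)
            )
    return SimConfig(
        n_prescriptions=n_prescriptions,
        disease_prevalence=diseases,
        medications=medications,
        indication_map=indication_map,
        comorbidity_pairs=comorbidity_pairs,
        background_med_rate=background_med_rate,
        error_rate=error_rate,
        max_dx=max_dx,
        max_meds=max_meds,
        seed=seed,
    )
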