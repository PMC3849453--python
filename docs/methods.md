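# Methods

## Data model and cleaning

A prescription is the transaction unit: an identifier, 1–3 diagnosis codes
and 1–15 medication codes. Codes are deduplicated on ingest (co-occurrence
is defined at prescription level, so within-record repeats carry no
information). Cleaning is record-level and partitions every input row into
exactly one outcome, tested as an invariant:

1. **invalid** — malformed row, missing code list, a code failing the
   vocabulary's validity pattern, or a code absent from a supplied mapping
   table. Default patterns are `^[0-9EV][0-9]{2,4}$` (ICD9-CM-like) and
   `^[A-Z][0-9]{2}[A-Z]{2}[0-9]{2}$` (ATC level-5-like); both are
   configuration, not policy.
2. **excluded category** — any code matching a user-supplied prefix list
   (e.g. whole code blocks one wants out of the analysis). Empty by default.
3. **cardinality** — deduplicated code counts outside `[1, 3]` diagnoses or
   `[1, 15]` medications. The bounds describe the claims format being
   emulated, not the method, and are configurable.

A record with any bad code is dropped wholly rather than partially kept:
partial retention would silently change the record's pair set, and the
counts report makes whole-record exclusion auditable.

## Association strength

Each DM/MM pair's 2×2 table is assembled from its co-occurrence count `a`,
the two item marginals and the corpus size N (`build_table` checks the
`a+b+c+d = N` identity on construction). Two Q modes are provided:

* **lift** (default): `a·N / ((a+b)(a+c))` — symmetric in the items,
  invariant to scaling all cells, the ratio of the joint probability to its
  value under independence;
* **relative risk**: `(a/(a+b)) / (c/(c+d))` — asymmetric; equals `+inf`
  when the medication never occurs without the disease. Both modes are kept
  because either reading is defensible for this family of screens; the mode
  is recorded in the knowledge-base header so downstream classification is
  unambiguous.

Zero-denominator tables raise rather than return a sentinel; the miner
skips such pairs (they cannot arise for pairs that pass the support filter
in lift mode).

**Support filter.** Pairs with fewer than `min_support = 5` raw
co-occurrences are never materialized. Absent pairs are non-positive by
construction — this is the mechanism by which uncommon-or-rare
combinations trigger inappropriateness, so the filter is part of the model,
not an optimization.

**Significance filter.** With `fisher_alpha` set, each stored entry carries
the one-sided (greater) Fisher exact p-value of its table, and positivity
additionally requires `p < alpha`. The one-sided direction is deliberate:
the filter exists to prune *spuriously positive* associations. At desk
scale this filter matters: a pair of independent items with a few dozen
co-occurrences has mined lift ≈ 1 ± 0.15, so with a strict `Q > 1` rule
roughly half of all chance pairs would count as positive and mask genuinely
rare medications; requiring significance reduces that per-pair false-cover
probability to ≈ alpha. The Fisher computation delegates to
`scipy.stats.fisher_exact`; the test suite checks it against exhaustive
enumeration of all tables with N ≤ 30 in exact rational arithmetic, to
1e-12.

**Thresholds.** `Q == q_threshold` is *not* positive (the cut-off is
strict, "greater than 1 indicates positive"). The knowledge-base file
stores n_prescriptions, min_support, q_mode, q_threshold and fisher_alpha
in its header; loading a file without them is a fatal format error, because
verdicts are only reproducible given the thresholds.

## Classification

Rule 1 counts *distinct* positive DM pairs plus distinct positive MM pairs
within the prescription and compares the sum to the medication count m —
the natural reading of the requirement; the alternative reading (each kind
separately ≥ m) is strictly harsher and is not implemented. For a
single-diagnosis, single-medication prescription all three rules collapse
to "the one DM pair is positive", which is also exactly what the lenient
mode (`appropriate iff ≥ 1 positive DM pair`) checks; lenient mode is
offered because the one-positive-pair criterion is a common simplification
for multi-item prescriptions, and comparing the two modes on the same
corpus is informative. Audit lists (positive pairs, uncovered diagnoses,
uncovered medications) are sorted, so re-classification is bit-identical.

Useful monotonicities, all property-tested: adding a positive entry to the
knowledge base can only flip verdicts toward appropriate; raising the Q
cut-off can only flip them away.

## Evaluation

`appropriate` is the positive class: PPV then reads as "how often an
appropriate call is right" and NPV as "how often a flag is right".
References marked `unknown` are excluded from all four denominators and
reported separately. A metric with an empty denominator is `None`, never 0.
Wilson score intervals (via `statsmodels`) are attached to every defined
metric; Wilson is preferred over Wald because several of these proportions
sit near 1.

## The synthetic claims generator

The generator is the package's test bed: it produces corpora whose
association structure is known in closed form, with the minimal set of
mechanisms the mining and classification stack must cope with —

* **skewed disease frequencies** (Zipf-profile prevalences) exercising the
  support filter across three orders of magnitude of pair counts;
* **indications**: each disease carries a block of medications with high
  conditional prescribing probabilities (the positive associations to be
  recovered);
* **comorbidity links** `(d_a, d_b, excess)`: having d_a adds d_b with the
  excess probability, which gives d_a a genuine but *indirect* lift on
  d_b's medications — the classic confounded association (a
  hypertension-style code acquiring lift with an insulin-style drug). The
  tests verify both that the confounded lift is mined and that it vanishes
  when stratified on the confounder;
* **background medications**: each medication independently appears with a
  small disease-independent probability (incidental co-prescriptions);
* **injected errors**: with probability `error_rate` one medication is
  replaced by one indicated for *none* of the present diseases; exactly
  those records are labelled inappropriate in the ground truth.

Sampling is vectorized and driven by a single `numpy` Generator seeded from
the config, so corpora are bit-reproducible. Cardinality bounds are
enforced by rejection (redraw until the count is in range), which makes the
record distribution the *exact* conditional law — that is what allows
`expected_lift` to be an exact oracle rather than an approximation: it
enumerates the diagnosis law in full (including comorbidity branching and
the `[1, max_dx]` conditioning; feasible up to 18 diseases) and handles the
`[1, max_meds]` medication conditioning with a Poisson-binomial tail
computation per diagnosis pattern. `expected_lift` does not model the
error-injection step, so it describes the pre-error association structure
and is exact when `error_rate = 0`; with the default 5% error rate the
perturbation of mined lifts is far below the Monte-Carlo noise at the
corpus sizes used.

### Default corpus (`make_config`)

| parameter | default | rationale |
|---|---|---|
| n_prescriptions | 100,000 | large enough that planted pairs have ≥ several hundred co-occurrences, small enough to simulate in seconds |
| n_diseases / n_medications | 60 / 240 | 60×3 indicated medications in disjoint blocks plus 60 never-indicated medications reachable only as background or errors |
| prevalence profile | Zipf, scaled to E[diagnoses] = 1.3 pre-conditioning | skewed frequencies, tail diseases still well-supported at n = 100,000 |
| indication probabilities | 0.8 / 0.85 / 0.9 per block | strong prescribing structure |
| comorbidity | 3 pairs, excess 0.3 | enough to exercise confounding without dominating the corpus |
| background_med_rate | 2·10⁻⁴ per medication | ≈ 4.7% of records carry one incidental medication. This parameter effectively *lower-bounds the model's false-alarm rate*: any sufficiently rare medication fails rule 3 regardless of the corpus size, so the incidental-prescription share is chosen to be a realistic few percent |
| error_rate | 0.05 | a visible but minority error class |

End-to-end runs mine the knowledge base on one corpus and classify a
freshly simulated corpus from the same configuration under a different seed
(a train-year/test-year split), with the Fisher filter at alpha = 0.05 —
the configuration under which the error-detection properties (sensitivity
for injected errors ≥ 0.8, false-positive rate ≤ 0.1) are tested across
five seeds.

### What the generator does not emulate

No patient-level longitudinality (refills, episodes), no age/sex/provider
effects, no dose or duration, no code-hierarchy structure, and indications
are mutually disjoint blocks rather than overlapping formularies. Passing
tests therefore show that the mining and rule stack recovers the structure
this generative family plants — not that the pipeline achieves any
particular accuracy on real claims, where appropriateness is confounded by
everything the generator omits.

## Numerical choices

* Q values are stored and serialized with full float precision (`repr`);
  knowledge-base round trips are bit-exact.
* Ties at the threshold (`Q == cut-off`, `p == alpha`) are non-positive /
  non-significant (strict inequalities).
* MM pairs are canonicalized by lexicographic code order everywhere.
* All iteration orders in verdicts and serialized files are sorted, so
  every artifact is byte-reproducible.
* Degenerate inputs fail loudly: empty corpus, zero-denominator Q,
  unlabelled verdict at evaluation, knowledge-base file missing a
  threshold field.

## Problem sizes used by the test suite

Calibration and recovery checks run at 100,000 prescriptions (five seeds
for the independence calibration and the error-detection property; one
corpus for parameter recovery against the analytic oracle, tolerance 10%
relative on well-supported pairs). The Fisher implementation is swept
against exact enumeration over every table with N ≤ 30. Counting is
verified exactly against brute force on 100 random corpora of up to 50
prescriptions. These sizes keep the full suite under a few minutes while
leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The model is purely associational: it will happily endorse a confounded
  combination (the Fisher filter removes chance associations, not
  confounded ones — stratified analysis, which the tests demonstrate,
  would be needed for that) and it has no notion of dose, duration,
  interaction or contraindication.
* False-alarm behaviour is structural: any medication rare for the
  recorded diagnoses is flagged, including legitimately unusual therapy and
  newly introduced drugs with no prescribing history.
* The relative-risk mode shares the lift mode's support filter but not its
  symmetry; published cut-offs for one are not transferable to the other.
* `expected_lift` requires full enumeration of the diagnosis law and is
  limited to configurations with ≤ 18 diseases; it is an oracle for tests
  and small studies, not a large-scale tool.
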