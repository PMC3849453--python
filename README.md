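# aopmine

Association mining for prescription claims, and a rule-based check of the
appropriateness of a prescription (AOP).

## The problem

Most medication errors that reach patients involve a drug that is *unusual*
for the patient's recorded diagnoses. Given a large claims corpus — each
prescription carrying 1–3 diagnosis codes (ICD9-CM style) and 1–15
medication codes (ATC style) — commonly co-prescribed disease–medication
combinations can be taken as presumptively appropriate, and rare ones as
worth an alert, without any curated guideline knowledge. `aopmine`
implements that idea end to end for epidemiologists and clinical-informatics
researchers: cleaning claims extracts, mining pairwise association
strengths, classifying prescriptions, and evaluating the classifier.

## The model

For every disease–medication (DM) and medication–medication (MM) pair,
co-occurrence is counted at prescription level and summarized in a 2×2
table (a = both, b = X only, c = Y only, d = neither, N = a+b+c+d). The
association strength Q is the lift

    Q = P(X,Y) / (P(X) · P(Y)) = a·N / ((a+b)(a+c))

(Q = 1: independent; Q > 1: positively associated; Q < 1: negative).
Relative risk, (a/(a+b)) / (c/(c+d)), is available as an alternative mode.
Pairs with fewer than 5 co-occurrences are treated as uncommon-or-rare and
never enter the knowledge base; optionally a one-sided Fisher exact test
prunes pairs whose excess co-occurrence is not significant, which removes
chance associations and flags confounded ones.

A prescription with m medications is **appropriate** iff, over the pairs it
contains whose Q strictly exceeds the cut-off (default 1):

1. (# positive DM pairs) + (# positive MM pairs) ≥ m,
2. every diagnosis takes part in ≥ 1 positive DM pair,
3. every medication takes part in ≥ 1 positive DM or MM pair.

Verdicts carry a per-rule audit trail (which diagnoses/medications are
uncovered). Evaluation against reference labels reports sensitivity,
specificity, PPV and NPV with "appropriate" as the positive class, Wilson
score intervals included, and `unknown` references excluded from every
denominator.

Because real national-scale claims data cannot be redistributed, the
package ships a synthetic claims simulator with skewed disease prevalences,
probabilistic indications, comorbidity links (which reproduce confounded
associations such as a hypertension-style diagnosis acquiring lift with an
insulin-style drug), incidental background medications, and injected
rare-medication errors with ground-truth labels. The simulator comes with
an exact analytic oracle (`expected_lift`) for the lift any pair should
show, which the tests use to validate the mining stack.

## Worked example

```bash
python examples/end_to_end_evaluation.py
```

mines a knowledge base from 50,000 simulated prescriptions and classifies a
second, independently simulated corpus containing 5% injected errors:

```
mined 5727 DM + 7929 MM pairs from 50000 prescriptions
classified 50000 fresh prescriptions: 0.907 appropriate, 0.093 flagged

against ground truth (positive class = appropriate):
  sensitivity  0.952  (95% Wilson CI 0.950-0.954)
  specificity  0.990  (95% Wilson CI 0.985-0.993)
  ppv          0.999  (95% Wilson CI 0.999-1.000)
  npv          0.508  (95% Wilson CI 0.494-0.523)

injected errors caught: 2361/2385 (99.0%)
```

99% of the injected errors are flagged (specificity), almost every
"appropriate" call is correct (PPV), and about half of the flags are false
alarms (NPV) — the price of alerting on *any* rare combination.
`examples/mine_associations.py` shows mined Q values against the
generator's analytic lift, and `examples/check_prescriptions.py` walks the
three rules on individual prescriptions.

The same pipeline is scriptable from the shell:

```bash
aop simulate --n 50000 --seed 1 --out claims.tsv --truth truth.tsv
aop mine --input claims.tsv --min-support 5 --fisher-alpha 0.05 --out kb.tsv
aop classify --kb kb.tsv --input claims.tsv --out verdicts.tsv
aop evaluate --verdicts verdicts.tsv --labels truth.tsv --out report.tsv
aop run --n 50000 --seed 1 --outdir out/        # all four stages at once
```

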