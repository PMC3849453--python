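"""Classify individual prescriptions and inspect the per-rule audit trail.

Mines a knowledge base from an error-free corpus, then classifies one
ordinary prescription and one carrying a medication that is rare for its
diagnosis, printing which of the three appropriateness rules fired.
"""

from aopmine import PrescriptionRecord, build_knowledge_base, classify, simulate
from aopmine.simulate import disease_code, make_config, medication_code

cfg = make_config(30_000, n_diseases=8, n_medications=32, error_rate=0.0, seed=1)
records, _ = simulate(cfg)
kb = build_knowledge_base(records, fisher_alpha=0.05)
print(f"mined {len(kb.dm)} DM + {len(kb.mm)} MM associations "
      f"(Q cut-off {kb.q_threshold}, Fisher alpha {kb.fisher_alpha})\n")

dx = disease_code(0)
good = PrescriptionRecord("rx-good", (dx,), (medication_code(0), medication_code(1)))
# medication_code(29) is indicated for no disease in this configuration
bad = PrescriptionRecord("rx-bad", (dx,), (medication_code(0), medication_code(29)))

for rx in (good, bad):
    v = classify(rx, kb)
    verdict = "appropriate" if v.appropriate else "INAPPROPRIATE"
    print(f"{rx.rx_id}: dx={rx.diagnoses} meds={rx.medications} -> {verdict}")
    print(f"  rule1 (enough positive pairs):    {v.rule1_pass}")
    print(f"  rule2 (every dx covered):         {v.rule2_pass}"
          + (f"  offending: {v.offending_diagnoses}" if not v.rule2_pass else ""))
    print(f"  rule3 (every med covered):        {v.rule3_pass}"
          + (f"  offending: {v.offending_medications}" if not v.rule3_pass else ""))
    print(f"  positive DM pairs: {v.positive_dm}")
    print(f"  positive MM pairs: {v.positive_mm}\n")

print("The second prescription is flagged because its extra medication has no")
print("positive association with the recorded diagnosis or the co-medications:")
print("exactly the uncommon/rare combination the model is built to alert on.")
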