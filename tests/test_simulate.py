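"""The synthetic claims generator and its analytic lift oracle."""

import itertools

import pytest

from aopmine import (
    SimConfig,
    SimulationError,
    build_table,
    compute_q,
    count_pairs,
    expected_lift,
    read_prescriptions,
    simulate,
    write_prescriptions,
)
from aopmine.simulate import disease_code, make_config, medication_code


def two_disease_config(**overrides):
    base = dict(
        n_prescriptions=2000,
        disease_prevalence={"401": 0.9, "250": 0.2},
        medications=["Z00AA01", "M00AA01", "X00AA01"],
        indication_map={"401": [("Z00AA01", 1.0)], "250": [("M00AA01", 0.9)]},
        background_med_rate=0.01,
        error_rate=0.0,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestSimulate:
    def test_same_seed_reproduces_corpus(self):
        cfg = make_config(2000, seed=5)
        r1, t1 = simulate(cfg)
        r2, t2 = simulate(make_config(2000, seed=5))
        assert r1 == r2 and t1 == t2

    def test_different_seed_changes_corpus(self):
        assert simulate(make_config(2000, seed=1))[0] != simulate(make_config(2000, seed=2))[0]

    def test_zero_error_rate_all_appropriate(self):
        _, truth = simulate(two_disease_config())
        assert set(truth.labels.values()) == {"appropriate"}
        assert truth.n_inappropriate == 0

    def test_ground_truth_marks_exactly_the_injected_records(self):
        records, truth = simulate(make_config(5000, error_rate=0.1, seed=3))
        by_id = {r.rx_id: r for r in records}
        n_bad = 0
        for rx_id, label in truth.labels.items():
            errors = truth.errors_for(rx_id)
            assert (label == "inappropriate") == (len(errors) >= 1)
            for med in errors:
                assert med in by_id[rx_id].medications
                n_bad += 1
        assert 0 < n_bad < 0.2 * len(records)

    def test_cardinality_bounds_respected(self):
        records, _ = simulate(make_config(3000, seed=2))
        assert all(1 <= r.n_diagnoses <= 3 for r in records)
        assert all(1 <= r.n_medications <= 15 for r in records)

    def test_generated_corpus_survives_default_cleaning_untouched(self, tmp_path):
        records, _ = simulate(make_config(500, seed=4))
        path = tmp_path / "claims.tsv"
        write_prescriptions(records, path)
        back, report = read_prescriptions(path)
        assert back == records
        assert report.n_dropped == 0

    def test_infeasible_error_config_is_fatal(self):
        cfg = two_disease_config(
            medications=["Z00AA01"],
            indication_map={"401": [("Z00AA01", 1.0)], "250": [("Z00AA01", 0.9)]},
            error_rate=0.1,
        )
        with pytest.raises(SimulationError, match="candidate"):
            simulate(cfg)

    def test_config_dict_round_trip(self):
        cfg = make_config(1000, seed=9)
        assert SimConfig.from_dict(cfg.to_dict()) == cfg

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            two_disease_config(disease_prevalence={"401": 1.2, "250": 0.2}).validate()


def oracle_two_disease_lift(cfg, disease, medication):
    """Independent enumeration for two-disease, no-comorbidity configs.

    Walks the four base diagnosis draws and all medication subsets
    explicitly, applying the same [1, max] conditioning the sampler's
    rejection loops realize.
    """
    codes = list(cfg.disease_prevalence)
    prev = [cfg.disease_prevalence[c] for c in codes]
    ind = {
        d: {m: p for m, p in cfg.indication_map.get(d, [])}
        for d in codes
    }
    p_d = p_m = p_dm = norm = 0.0
    for present in itertools.product([False, True], repeat=2):
        p_vec = 1.0
        for flag, pr in zip(present, prev):
            p_vec *= pr if flag else 1.0 - pr
        n_dx = sum(present)
        if not (1 <= n_dx <= cfg.max_dx):
            continue
        norm += p_vec
        med_p = {}
        for m in cfg.medications:
            miss = 1.0 - cfg.background_med_rate
            for flag, d in zip(present, codes):
                if flag:
                    miss *= 1.0 - ind[d].get(m, 0.0)
            med_p[m] = 1.0 - miss
        pm_given = pc = 0.0
        for subset in itertools.product([False, True], repeat=len(cfg.medications)):
            p_sub = 1.0
            for has, m in zip(subset, cfg.medications):
                p_sub *= med_p[m] if has else 1.0 - med_p[m]
            if 1 <= sum(subset) <= cfg.max_meds:
                pc += p_sub
                if subset[cfg.medications.index(medication)]:
                    pm_given += p_sub
        pm_given /= pc
        p_m += p_vec * pm_given
        if present[codes.index(disease)]:
            p_d += p_vec
            p_dm += p_vec * pm_given
    p_d, p_m, p_dm = p_d / norm, p_m / norm, p_dm / norm
    return p_dm / (p_d * p_m)


class TestExpectedLift:
    def test_independent_medication_has_lift_one(self):
        # second medication of the always-present disease, drawn independently
        cfg = two_disease_config(
            indication_map={
                "401": [("Z00AA01", 1.0), ("X00AA01", 0.3)],
                "250": [("M00AA01", 0.9)],
            },
            disease_prevalence={"401": 1.0, "250": 0.2},
            background_med_rate=0.0,
        )
        assert expected_lift(cfg, "250", "X00AA01") == pytest.approx(1.0)

    def test_matches_independent_enumeration(self):
        cfg = two_disease_config()
        for d, m in [("250", "M00AA01"), ("401", "Z00AA01"), ("250", "Z00AA01")]:
            assert expected_lift(cfg, d, m) == pytest.approx(
                oracle_two_disease_lift(cfg, d, m), rel=1e-9
            )

    def test_planted_indication_yields_positive_mined_lift(self):
        cfg = two_disease_config(n_prescriptions=50_000, seed=12)
        records, _ = simulate(cfg)
        counts = count_pairs(records)
        table = build_table(
            counts.dm[("250", "M00AA01")],
            counts.dx_marginals["250"],
            counts.med_marginals["M00AA01"],
            counts.n_prescriptions,
        )
        mined = compute_q(table)
        expected = expected_lift(cfg, "250", "M00AA01")
        assert expected > 1.5
        assert mined > 1.0
        assert mined == pytest.approx(expected, rel=0.1)

    def test_unknown_item_rejected(self):
        cfg = two_disease_config()
        with pytest.raises(ValueError, match="unknown disease"):
            expected_lift(cfg, "999", "M00AA01")
        with pytest.raises(ValueError, match="unknown medication"):
            expected_lift(cfg, "250", "Q99ZZ99")

    def test_zero_marginal_is_undefined(self):
        cfg = two_disease_config(background_med_rate=0.0)
        # X00AA01 is indicated nowhere and has no background mass
        with pytest.raises(ValueError, match="zero marginal"):
            expected_lift(cfg, "250", "X00AA01")


class TestConfounding:
    def config(self, n=30_000, seed=21):
        # hypertension-like disease A drags in diabetes-like disease B,
        # whose medication then co-occurs with A without being indicated
        return SimConfig(
            n_prescriptions=n,
            disease_prevalence={"401": 0.3, "250": 0.1, "493": 0.4},
            medications=["C00AA01", "A00AA01", "R00AA01"],
            indication_map={
                "401": [("C00AA01", 0.9)],
                "250": [("A00AA01", 0.9)],
                "493": [("R00AA01", 0.9)],
            },
            comorbidity_pairs=[("401", "250", 0.5)],
            background_med_rate=0.005,
            error_rate=0.0,
            seed=seed,
        )

    def test_expected_lift_of_non_indicated_disease_exceeds_one(self):
        assert expected_lift(self.config(), "401", "A00AA01") > 1.3

    def test_mined_lift_reproduces_the_confounded_association(self):
        cfg = self.config()
        records, _ = simulate(cfg)
        counts = count_pairs(records)
        table = build_table(
            counts.dm[("401", "A00AA01")],
            counts.dx_marginals["401"],
            counts.med_marginals["A00AA01"],
            counts.n_prescriptions,
        )
        mined = compute_q(table)
        assert mined > 1.0
        assert mined == pytest.approx(expected_lift(cfg, "401", "A00AA01"), rel=0.15)

    def test_association_vanishes_when_stratified_on_the_confounder(self):
        # restricted to records without the comorbid disease, the lift of the
        # non-indicated pair returns to ~1: the association is indirect
        records, _ = simulate(self.config())
        stratum = [r for r in records if "250" not in r.diagnoses]
        counts = count_pairs(stratum)
        table = build_table(
            counts.dm[("401", "A00AA01")],
            counts.dx_marginals["401"],
            counts.med_marginals["A00AA01"],
            counts.n_prescriptions,
        )
        assert compute_q(table) == pytest.approx(1.0, abs=0.3)


class TestCodeHelpers:
    def test_codes_match_default_patterns(self):
        from aopmine.records import Vocabulary

        dx, med = Vocabulary.diagnosis(), Vocabulary.medication()
        assert all(dx.is_wellformed(disease_code(i)) for i in range(0, 900, 97))
        assert all(med.is_wellformed(medication_code(i)) for i in range(0, 2600, 211))
        assert len({medication_code(i) for i in range(2600)}) == 2600
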