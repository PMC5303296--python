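"""Synthetic cohort generation, MCAR degradation and UCI ingestion."""

import numpy as np
import pytest

from plausikb import DegradationSpec, generate_synthetic_cohort, mcar_degrade
from plausikb.datasets import (N_ATTRIBUTES, REFERENCE_N,
                               attribute_facts, hepatitis_ontology, missing_slots,
                               read_uci_hepatitis)


@pytest.fixture(scope="module")
def cohort():
    onto = hepatitis_ontology()
    kb, labels = generate_synthetic_cohort(seed=1, ontology=onto)
    return kb, labels


class TestGenerator:
    def test_reference_slot_accounting(self, cohort):
        kb, labels = cohort
        assert len(labels) == REFERENCE_N
        assert N_ATTRIBUTES == 19
        present = attribute_facts(kb)
        # 155 x 19 = 2945 slots; the reference cohort leaves 167 empty
        assert len(present) + missing_slots(kb) == 2945
        assert missing_slots(kb) == 167

    def test_same_seed_reproduces_kb_and_labels(self):
        a_kb, a_labels = generate_synthetic_cohort(seed=9)
        b_kb, b_labels = generate_synthetic_cohort(seed=9)
        assert {f.key for f in a_kb.facts()} == {f.key for f in b_kb.facts()}
        assert a_labels == b_labels

    def test_categorical_means_match_reference_distribution(self):
        pos = []
        for seed in range(50):
            kb, _ = generate_synthetic_cohort(seed=seed)
            pos.append(sum(1 for f in kb.facts()
                           if f.attribute == "antivirals" and f.predicate == "onMed"))
        mean = np.mean(pos)
        # Binomial(155, 131/155): SE of a 50-seed mean ~ 0.64
        assert abs(mean - 131) < 3 * 0.64 + 0.5

    def test_enrichment_assigns_instances(self, cohort, onto):
        kb, _ = cohort
        meds = {f.value for f in kb.facts_for("onMed")}
        assert meds <= {"Cortisone", "Prednisone", "Dexamethasone",
                        "InterferonAlfa2", "Lamivudine", "Adefovir"}
        diseases = {f.value for f in kb.facts_for("hasDisease")}
        assert diseases == {"hepatitis_A", "hepatitis_B", "hepatitis_C"}
        ages = [f.value for f in kb.facts_for("age")]
        assert len(ages) == REFERENCE_N and all(7 <= a <= 78 for a in ages)

    def test_rejects_empty_cohort(self):
        with pytest.raises(ValueError):
            generate_synthetic_cohort(n=0)


class TestMcar:
    def test_zero_fraction_keeps_kb_unchanged(self, cohort):
        kb, _ = cohort
        (rep,) = mcar_degrade(kb, DegradationSpec(0.0, replicates=1, seed=4))
        assert {f.key for f in rep.kb.facts()} == {f.key for f in kb.facts()}
        assert rep.total_missing == missing_slots(kb)

    def test_degradation_only_removes_attribute_facts(self, cohort):
        kb, _ = cohort
        (rep,) = mcar_degrade(kb, DegradationSpec(0.5, replicates=1, seed=4))
        removed = {f.key for f in kb.facts()} - {f.key for f in rep.kb.facts()}
        assert removed, "expected removals at p=0.5"
        assert {f.key for f in rep.kb.facts()} <= {f.key for f in kb.facts()}
        kept_types = {f.key for f in rep.kb.facts_for("type")}
        assert kept_types == {f.key for f in kb.facts_for("type")}
        assert {f.key for f in rep.kb.facts_for("hasDisease")} == \
               {f.key for f in kb.facts_for("hasDisease")}

    def test_removal_count_matches_binomial_expectation(self, cohort):
        kb, _ = cohort
        p = 0.1
        present = len(attribute_facts(kb))
        reps = mcar_degrade(kb, DegradationSpec(p, replicates=200, seed=11))
        removed = np.array([r.removed for r in reps])
        expectation = p * present
        se = np.sqrt(present * p * (1 - p) / len(reps))
        assert abs(removed.mean() - expectation) < 3 * se
        # total missing = pre-existing + removed, always
        assert all(r.total_missing == missing_slots(kb) + r.removed for r in reps)

    def test_fraction_validation(self, cohort):
        with pytest.raises(ValueError):
            DegradationSpec(1.5)


class TestUciReader:
    def _write_csv(self, path, rows):
        path.write_text("\n".join(",".join(str(v) for v in r) for r in rows) + "\n")

    def test_small_file_parses_to_expected_facts(self, tmp_path, onto):
        # class,age,sex,steroids,antivirals,fatigue,malaise,anorexia,bigLiver,
        # firmLiver,spleen,spiders,ascites,varices,bili,alk,sgot,albumin,protime,histology
        rows = [
            [2, 30, 1, 1, 2, 2, "?", 1, 2, 2, 2, 1, 2, 2, 0.9, 95, 28, 4.0, 75, 1],
            [1, 50, 2, 2, 1, 1, 2, 2, "?", 1, 1, 2, 1, 1, "?", 120, 60, 3.1, "?", 2],
        ]
        path = tmp_path / "hep.csv"
        self._write_csv(path, rows)
        kb, labels = read_uci_hepatitis(path, enrich=False, ontology=onto)
        assert labels == {"p1": True, "p2": False}
        assert kb.holds("sex", "p1", "male") and kb.holds("sex", "p2", "female")
        assert kb.holds("physicalSign", "p1", "ascites")
        assert kb.holds("noPhysicalSign", "p2", "ascites")
        assert kb.holds("age", "p1", 30)
        # '?' emits neither a positive nor a negative fact
        assert not kb.holds("symptom", "p1", "malaise")
        assert not kb.holds("noSymptom", "p1", "malaise")
        assert not any(f.predicate == "live" for f in kb.facts())

    def test_enrichment_is_seeded(self, tmp_path):
        rows = [[2, 30, 1, 2, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1.0, 100, 30, 4.0, 80, 1]]
        path = tmp_path / "hep.csv"
        self._write_csv(path, rows)
        a, _ = read_uci_hepatitis(path, enrich=True, seed=3)
        b, _ = read_uci_hepatitis(path, enrich=True, seed=3)
        assert {f.key for f in a.facts()} == {f.key for f in b.facts()}
        assert any(f.predicate == "hasDisease" for f in a.facts())

    def test_wrong_column_count_is_fatal(self, tmp_path):
        path = tmp_path / "hep.csv"
        self._write_csv(path, [[1, 2, 3]])
        with pytest.raises(Exception):
            read_uci_hepatitis(path)
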