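"""Fact/rule model, rule-dialect parsing and knowledge-base I/O."""

import random

import pytest

from plausikb import (DeductiveRule, Fact, KnowledgeBase, PlausibleRule,
                      RuleSyntaxError, load_kb, match_facts, parse_literal_text,
                      parse_rule_text, save_kb_text, save_kb_turtle, serialize_rule)
from plausikb.model import Const, Var, fingerprint_rule
from plausikb.ruleio import serialize_rules

ASCITES_RULE = ("physicalSign(P, ascites) :- onMed(P, (type Antiviral)), "
                "physicalSign(P, spleenPalpable).")


class TestRuleDialect:
    def test_deductive_rule_structure(self):
        (rule,) = parse_rule_text(ASCITES_RULE)
        assert isinstance(rule, DeductiveRule)
        assert rule.head.predicate == "physicalSign"
        assert len(rule.body) == 2
        assert rule.body[0].type_constraints == {"_T1": "Antiviral"}

    def test_plausible_rule_structure(self):
        (rule,) = parse_rule_text(
            "physicalSign(X, (type LiverIssue) L) <~ physicalSign(X, (type VeinIssue) V).")
        assert isinstance(rule, PlausibleRule)
        assert rule.consequent_type == "LiverIssue"
        assert rule.condition_type == "VeinIssue"

    @pytest.mark.parametrize("text", [
        ASCITES_RULE,
        "live(P, true) :- age(P, A), lessThan(A, 60), type(P, LiverDiseasePatient).",
        "physicalSign(X, (type LiverIssue) L) <~ physicalSign(X, (type VeinIssue) V).",
        "noPhysicalSign(P, bigLiver) :- onMed(P, (type Antiviral)).",
        "bilirubin(P, 2.5) :- pathology(P, histology).",
    ])
    def test_round_trip_identity(self, text):
        rules = parse_rule_text(text)
        again = parse_rule_text(serialize_rules(rules))
        assert [fingerprint_rule(a) for a in again] == [fingerprint_rule(r) for r in rules]
        assert serialize_rules(again) == serialize_rules(rules)

    def test_malformed_line_is_all_or_nothing(self):
        text = ("symptom(P, fatigue) :- symptom(P, malaise).\n"
                "symptom(P fatigue) :- symptom(P, anorexia).\n"
                "symptom(P, anorexia) :- symptom(P, malaise).\n")
        with pytest.raises(RuleSyntaxError) as err:
            parse_rule_text(text)
        assert err.value.line == 2

    def test_capitalized_concept_names_are_constants(self):
        lit = parse_literal_text("type(p116, LiverDiseasePatient)")
        assert lit.args[1] == Const("LiverDiseasePatient")
        lit = parse_literal_text("onMed(P, InterferonAlfa2)")
        assert lit.args[0] == Var("P")
        assert lit.args[1] == Const("InterferonAlfa2")

    def test_unknown_construct_reports_position(self):
        with pytest.raises(RuleSyntaxError):
            parse_rule_text("physicalSign(P, (size big) X) :- symptom(P, malaise).")


class TestKnowledgeBase:
    def test_duplicate_assertion_is_noop(self):
        kb = KnowledgeBase()
        f = Fact("physicalSign", "p1", "ascites")
        assert kb.add_fact(f) is True
        assert kb.add_fact(f) is False
        assert len(kb) == 1

    def test_retract_inferred_restores_asserted_state(self):
        kb = KnowledgeBase()
        kb.add_fact(Fact("physicalSign", "p1", "ascites"))
        before = {f.key for f in kb.facts()}
        kb.assert_statement(Fact("physicalSign", "p1", "firmLiver"), provenance="analogy")
        kb.assert_statement(Fact("type", "p1", "Patient"), provenance="ontology")
        assert len(kb) == 3
        kb.retract_inferred()
        assert {f.key for f in kb.facts()} == before

    def test_provenance_partition_is_conserved(self, case):
        kb, _, _, plaus = case
        n_asserted = len(kb.asserted)
        from plausikb import justify_query, parse_literal_text
        justify_query(kb, kb.ontology, plaus, parse_literal_text("live(p116, true)"))
        assert len(kb.asserted) == n_asserted

    def test_asserted_fact_cannot_move_partitions(self):
        kb = KnowledgeBase()
        kb.add_fact(Fact("symptom", "p1", "fatigue"))
        kb.assert_statement(Fact("symptom", "p1", "fatigue"), provenance="analogy")
        assert kb.get("symptom", "p1", "fatigue").provenance == "asserted"

    def test_frozen_kb_rejects_new_ground_truth(self):
        kb = KnowledgeBase()
        kb.freeze()
        with pytest.raises(Exception):
            kb.add_fact(Fact("symptom", "p1", "fatigue"))
        kb.assert_statement(Fact("symptom", "p1", "fatigue"), provenance="analogy")

    def test_induced_rule_participates_until_retracted(self, onto):
        from plausikb import backward_chain
        kb = KnowledgeBase(ontology=onto)
        kb.add_fact(Fact("symptom", "p1", "malaise"))
        rule = parse_rule_text("physicalSign(P, firmLiver) :- symptom(P, malaise).")[0]
        query = parse_literal_text("physicalSign(p1, firmLiver)")
        assert not backward_chain(kb, onto, query).complete
        kb.assert_statement(rule, provenance="induction")
        assert backward_chain(kb, onto, query).complete
        kb.retract_inferred()
        assert not backward_chain(kb, onto, query).complete


class TestLoadKb:
    def test_turtle_snippet_round_trip(self, tmp_path, onto):
        kb = KnowledgeBase()
        kb.add_fact(Fact("type", "p116", "Patient"))
        kb.add_fact(Fact("hasDisease", "p116", "hepatitis_B"))
        kb.add_fact(Fact("age", "p116", 38))
        kb.add_fact(Fact("physicalSign", "p116", "varices"))
        path = tmp_path / "p116.ttl"
        save_kb_turtle(kb, path)
        loaded = load_kb(path, ontology=onto)
        assert {f.key for f in loaded.facts()} == {f.key for f in kb.facts()}
        assert all(f.provenance == "asserted" for f in loaded.facts())

    def test_predicate_text_round_trip(self, tmp_path):
        kb = KnowledgeBase()
        kb.add_fact(Fact("physicalSign", "p1", "ascites"))
        kb.add_fact(Fact("bilirubin", "p1", 2.5))
        path = tmp_path / "kb.facts"
        save_kb_text(kb, path)
        loaded = load_kb(path)
        assert {f.key for f in loaded.facts()} == {f.key for f in kb.facts()}

    def test_empty_file_gives_empty_kb(self, tmp_path):
        path = tmp_path / "empty.facts"
        path.write_text("")
        assert len(load_kb(path)) == 0

    def test_loading_twice_is_idempotent(self, tmp_path):
        path = tmp_path / "kb.facts"
        path.write_text("physicalSign(p1, ascites).\n")
        kb = load_kb(path)
        for fact in load_kb(path).facts():
            kb.add_fact(fact)
        assert len(kb) == 1

    def test_unknown_predicate_strict_vs_lenient(self, tmp_path):
        path = tmp_path / "kb.facts"
        path.write_text("shoeSize(p1, large).\n")
        with pytest.raises(Exception):
            load_kb(path, known_predicates={"physicalSign"}, strict=True)
        kb = load_kb(path, known_predicates={"physicalSign"}, strict=False)
        assert len(kb) == 0


class TestMatchFacts:
    def test_constant_pattern(self, case):
        kb, _, _, _ = case
        bindings = match_facts(kb, parse_literal_text("physicalSign(P, ascites)"),
                               kb.ontology)
        assert sorted(b["P"] for b in bindings) == ["p23", "p45", "p67"]

    def test_empty_kb_matches_nothing(self, onto):
        kb = KnowledgeBase()
        assert match_facts(kb, parse_literal_text("physicalSign(P, ascites)"), onto) == []

    def test_typed_pattern_equals_brute_force(self, onto):
        rng = random.Random(42)
        meds = ["InterferonAlfa2", "Lamivudine", "Adefovir", "Cortisone",
                "Prednisone", "Dexamethasone"]
        kb = KnowledgeBase(ontology=onto)
        for i in range(10):
            for m in rng.sample(meds, rng.randint(0, 3)):
                kb.add_fact(Fact("onMed", f"p{i}", m))
        pattern = parse_literal_text("onMed(P, (type Antiviral) M)")
        got = {(b["P"], b["M"]) for b in match_facts(kb, pattern, onto)}
        expected = {(f.subject, f.value) for f in kb.facts_for("onMed")
                    if onto.is_instance_of(f.value, "Antiviral")}
        assert got == expected

    def test_builtin_patterns_evaluate_not_match(self, onto):
        kb = KnowledgeBase(ontology=onto)
        assert match_facts(kb, parse_literal_text("lessThan(3, 60)"), onto) == [{}]
        assert match_facts(kb, parse_literal_text("lessThan(70, 60)"), onto) == []
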