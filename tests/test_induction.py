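"""Inductive rule generalization from shared features."""

from plausikb import (Fact, InductionConfig, KnowledgeBase, backward_chain,
                      common_features, induce_rules, materialize_types,
                      parse_literal_text, retrieve_sharing_entities)
from plausikb.unify import entity_satisfies


class TestRetrieveSharingEntities:
    def test_ascites_cohort(self, case):
        kb, _, _, _ = case
        premise = parse_literal_text("physicalSign(p116, ascites)")
        assert retrieve_sharing_entities(kb, premise) == ["p23", "p45", "p67"]

    def test_no_sharer(self, case):
        kb, _, _, _ = case
        premise = parse_literal_text("physicalSign(p116, spiders)")
        assert retrieve_sharing_entities(kb, premise) == []

    def test_equals_brute_force_scan(self, case):
        kb, _, _, _ = case
        premise = parse_literal_text("physicalSign(p116, spleenPalpable)")
        expected = sorted({f.subject for f in kb.facts()
                           if f.predicate == "physicalSign"
                           and f.value == "spleenPalpable" and f.subject != "p116"})
        assert retrieve_sharing_entities(kb, premise) == expected


class TestCommonFeatures:
    def test_ascites_sharers_yield_spleen_and_antiviral_type(self, case):
        kb, _, _, _ = case
        feats = common_features(kb, kb.ontology, ["p23", "p45", "p67"], "p116",
                                exclude=("physicalSign", "ascites"))
        assert [str(f) for f in feats] == [
            "onMed(P, (type Antiviral))", "physicalSign(P, spleenPalpable)"]

    def test_identical_fact_sets_return_every_nonblacklisted_feature(self, onto):
        kb = KnowledgeBase(ontology=onto)
        for p in ("a", "b", "t"):
            kb.add_fact(Fact("symptom", p, "fatigue"))
            kb.add_fact(Fact("sex", p, "male"))
            kb.add_fact(Fact("age", p, 40))
        feats = common_features(kb, onto, ["a", "b"], "t")
        # sex blacklisted, continuous age excluded
        assert [str(f) for f in feats] == ["symptom(P, fatigue)"]

    def test_generalization_requires_similarity_threshold(self, onto):
        kb = KnowledgeBase(ontology=onto)
        kb.add_fact(Fact("onMed", "a", "Lamivudine"))
        kb.add_fact(Fact("onMed", "t", "InterferonAlfa2"))
        feats = common_features(kb, onto, ["a"], "t")
        assert [str(f) for f in feats] == ["onMed(P, (type Antiviral))"]
        # consim(antiviral instance, steroid instance) = 2/(2+2+... ) below tau=0.5
        kb2 = KnowledgeBase(ontology=onto)
        kb2.add_fact(Fact("onMed", "a", "Cortisone"))
        kb2.add_fact(Fact("onMed", "t", "InterferonAlfa2"))
        sim = onto.consim("Cortisone", "InterferonAlfa2")
        feats2 = common_features(kb2, onto, ["a"], "t")
        assert (sim >= 0.5) == bool(feats2)


class TestInduceRules:
    def test_table_style_ascites_rule_is_top_candidate(self, case):
        kb, _, _, _ = case
        premise = parse_literal_text("physicalSign(p116, ascites)")
        candidates = induce_rules(kb, kb.ontology, premise)
        assert candidates, "expected at least one candidate"
        top = candidates[0]
        assert str(top.rule) == ("physicalSign(P, ascites) :- onMed(P, (type Antiviral)), "
                                 "physicalSign(P, spleenPalpable).")
        assert top.positive_coverage == 3
        assert top.supporting_entities == ["p23", "p45", "p67"]
        assert top.rule.provenance == "induction"
        assert any(step.generalized_to == "Antiviral" for step in top.trace)

    def test_no_sharers_no_rules(self, case):
        kb, _, _, _ = case
        premise = parse_literal_text("physicalSign(p116, spiders)")
        assert induce_rules(kb, kb.ontology, premise) == []

    def test_synthetic_coverage_count(self, onto):
        kb = KnowledgeBase(ontology=onto)
        for p in ("a", "b", "c", "d"):
            kb.add_fact(Fact("physicalSign", p, "spiders"))
            kb.add_fact(Fact("symptom", p, "malaise"))
        kb.add_fact(Fact("symptom", "t", "malaise"))
        premise = parse_literal_text("physicalSign(t, spiders)")
        (cand,) = induce_rules(kb, onto, premise)
        assert str(cand.rule) == "physicalSign(P, spiders) :- symptom(P, malaise)."
        assert cand.positive_coverage == 4

    def test_coverage_consistent_with_matching(self, case):
        kb, _, _, _ = case
        premise = parse_literal_text("physicalSign(p116, ascites)")
        for cand in induce_rules(kb, kb.ontology, premise):
            holders = {f.subject for f in kb.facts_for(cand.rule.head.predicate)
                       if f.value == cand.rule.head.args[1].value}
            recomputed = sorted(e for e in holders
                                if entity_satisfies(kb, kb.ontology, e, cand.rule.body))
            assert recomputed == cand.supporting_entities
            assert len(recomputed) == cand.positive_coverage
            assert entity_satisfies(kb, kb.ontology, "p116", cand.rule.body)

    def test_min_coverage_filter(self, case):
        kb, _, _, _ = case
        premise = parse_literal_text("physicalSign(p116, ascites)")
        assert induce_rules(kb, kb.ontology, premise,
                            config=InductionConfig(min_coverage=4)) == []

    def test_blacklisted_attribute_never_in_bodies(self, onto):
        kb = KnowledgeBase(ontology=onto)
        for p in ("a", "b", "t"):
            kb.add_fact(Fact("sex", p, "male"))
            kb.add_fact(Fact("symptom", p, "fatigue"))
        for p in ("a", "b"):
            kb.add_fact(Fact("physicalSign", p, "spiders"))
        premise = parse_literal_text("physicalSign(t, spiders)")
        for cand in induce_rules(kb, onto, premise):
            assert all(lit.predicate != "sex" for lit in cand.rule.body)

    def test_accepted_rule_makes_premise_provable(self, case):
        kb, _, _, _ = case
        materialize_types(kb, kb.ontology)
        premise = parse_literal_text("physicalSign(p116, ascites)")
        assert not backward_chain(kb, kb.ontology, premise).complete
        top = induce_rules(kb, kb.ontology, premise)[0]
        kb.assert_statement(top.rule, provenance="induction")
        assert backward_chain(kb, kb.ontology, premise).complete

    def test_continuous_binning_is_available_but_off_by_default(self, onto):
        kb = KnowledgeBase(ontology=onto)
        for p, age in [("a", 30), ("b", 32), ("t", 31)]:
            kb.add_fact(Fact("age", p, age))
            kb.add_fact(Fact("symptom", p, "fatigue"))
        default = common_features(kb, onto, ["a", "b"], "t")
        assert all(f.predicate != "age" for f in default)
        binned = common_features(kb, onto, ["a", "b"], "t",
                                 config=InductionConfig(bin_continuous=1))
        assert any(f.predicate == "age" for f in binned)
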