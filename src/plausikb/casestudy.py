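"""Reconstructed patient-p116 case-study fixture.

A small cohort exercising every reasoning strategy on one survival query:

* p116 — the queried (lesser-known) patient: young, hepatitis B, varices
  and a palpable spleen recorded, on InterferonAlfa2; ascites and firm
  liver *missing* from the record.
* p75 — the well-known reference entity: varices and a firm liver, so the
  vein->liver plausible rule can transfer ``firmLiver`` to p116.
* p23/p45/p67 — patients sharing ascites, a palpable spleen and (various)
  antiviral medications: the material for inducing
  ``physicalSign(P, ascites) :- onMed(P, (type Antiviral)), physicalSign(P, spleenPalpable).``

The survival rule and cohort records are SYNTHETIC reconstructions from the
published prose (the original rule bodies and dataset replicates are not
public) and are not clinically validated.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .datasets import hepatitis_ontology
from .model import Fact, KnowledgeBase
from .ontology import ConceptHierarchy
from .ruleio import parse_rule_text

SURVIVAL_RULES = """\
% Reconstructed survival rule: young liver-disease patients whose ascites and
% firm-liver findings are on record are justified as survivors.
live(P, true) :- age(P, A), lessThan(A, 60), type(P, LiverDiseasePatient), physicalSign(P, ascites), physicalSign(P, firmLiver).
"""

PLAUSIBLE_RULES = """\
% Entities sharing a vein issue plausibly share a liver issue.
physicalSign(X, (type LiverIssue) L) <~ physicalSign(X, (type VeinIssue) V).
"""


def case_rules() -> Tuple[list, list]:
    """(deductive rules, plausible rules) for the case study."""
    deductive = parse_rule_text(SURVIVAL_RULES)
    plausible = parse_rule_text(PLAUSIBLE_RULES)
    return deductive, plausible


def case_ontology() -> ConceptHierarchy:
    return hepatitis_ontology()


def case_kb(ontology: ConceptHierarchy = None) -> Tuple[KnowledgeBase, Dict[str, bool]]:
    """The case-study KB (asserted facts only) and its gold labels."""
    onto = ontology or case_ontology()
    kb = KnowledgeBase(ontology=onto)

    def patient(pid, **facts):
        kb.add_fact(Fact("type", pid, "Patient"))
        for pred, values in facts.items():
            if not isinstance(values, list):
                values = [values]
            for v in values:
                kb.add_fact(Fact(pred, pid, v))

    # queried patient: ascites and firmLiver are absent from the record
    patient("p116", age=38, hasDisease="hepatitis_B",
            physicalSign=["varices", "spleenPalpable"], onMed="InterferonAlfa2")
    # reference entity for the vein->liver analogy
    patient("p75", age=45, hasDisease="hepatitis_C",
            physicalSign=["varices", "firmLiver"])
    # ascites cohort backing the induced rule (records partially degraded)
    patient("p23", physicalSign=["ascites", "spleenPalpable"], onMed="Lamivudine")
    patient("p45", physicalSign=["ascites", "spleenPalpable"], onMed="Adefovir")
    patient("p67", physicalSign=["ascites", "spleenPalpable"], onMed="Lamivudine")
    for deductive in case_rules()[0]:
        kb.add_rule(deductive)
    labels = {"p116": True, "p75": True, "p23": True, "p45": False, "p67": True}
    return kb, labels
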