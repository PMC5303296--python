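"""Multi-strategy orchestration: ontology materialization -> deduction ->
analogy -> induction -> expert verification -> materialization.

Plausible inferences accumulate in a per-query *working memory* (a copy of
the KB); they are materialized into the shared KB only on explicit
acceptance.  Expert verification is modelled by a :class:`DecisionFile`
listing accepted/rejected fingerprints: in verified mode only accepted
items are used, so verified-mode answers are always a subset of the
without-verification answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import yaml

from .analogy import resolve_by_analogy
from .deduction import JustificationNode, backward_chain, missing_premises
from .induction import InductionConfig, induce_rules
from .model import (DeductiveRule, Fact, KnowledgeBase, Literal, PlausibleRule,
                    fingerprint_fact, fingerprint_rule)
from .ontology import ConceptHierarchy, materialize_types


@dataclass
class DecisionFile:
    """Batch record of an expert's accept/reject decisions.

    Fingerprints are canonical whitespace-free serializations of facts and
    rules, so decisions survive reformatting.
    """

    accepted_rules: set = field(default_factory=set)
    accepted_facts: set = field(default_factory=set)
    rejected_rules: set = field(default_factory=set)
    rejected_facts: set = field(default_factory=set)

    @staticmethod
    def _norm(fp: str) -> str:
        return fp.replace(" ", "")

    def accepts_fact(self, fact: Fact) -> bool:
        return fingerprint_fact(fact) in {self._norm(f) for f in self.accepted_facts}

    def accepts_rule(self, rule) -> bool:
        return fingerprint_rule(rule) in {self._norm(r) for r in self.accepted_rules}

    @classmethod
    def accept_all(cls) -> "DecisionFile":
        return _AcceptAll()

    @classmethod
    def load(cls, path) -> "DecisionFile":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            accepted_rules=set(data.get("accepted_rules", [])),
            accepted_facts=set(data.get("accepted_facts", [])),
            rejected_rules=set(data.get("rejected_rules", [])),
            rejected_facts=set(data.get("rejected_facts", [])),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "accepted_rules": sorted(self.accepted_rules),
            "accepted_facts": sorted(self.accepted_facts),
            "rejected_rules": sorted(self.rejected_rules),
            "rejected_facts": sorted(self.rejected_facts),
        }))


class _AcceptAll(DecisionFile):
    def accepts_fact(self, fact) -> bool:
        return True

    def accepts_rule(self, rule) -> bool:
        return True


@dataclass
class QueryResult:
    query: Literal
    answered: bool
    tree: JustificationNode
    plausible_rules_used: List[DeductiveRule] = field(default_factory=list)
    plausible_facts_used: List[Fact] = field(default_factory=list)
    verification_state: str = "unverified"
    answer_correctness: Optional[str] = None
    alternatives: dict = field(default_factory=dict)
    working_memory: Optional[KnowledgeBase] = None

    def score(self, gold_live: bool) -> str:
        """Label-based scoring of an answered survival query."""
        if not self.answered:
            return "unanswered"
        return "correct" if gold_live else "incorrect"


def justify_query(kb: KnowledgeBase, onto: ConceptHierarchy,
                  plausible_rules: Sequence[PlausibleRule], query: Literal,
                  strategy: str = "plausible",
                  decisions: Optional[DecisionFile] = None,
                  config: InductionConfig = InductionConfig(),
                  depth_limit: int = 25,
                  collect_alternatives: bool = False,
                  max_rounds: int = 20) -> QueryResult:
    """Justify a query, optionally supplementing deduction with plausible
    inference.

    ``strategy='deductive'`` stops after backward chaining (invariant to the
    plausible rule set).  ``strategy='plausible'`` then walks the missing
    premises in order, trying analogy first and induction second per
    premise; accepted inferences enter working memory and the tree is
    re-evaluated.  Without a decision file every candidate is used (the
    "without expert's verification" condition); with one, only accepted
    items are.
    """
    if strategy not in ("deductive", "plausible"):
        raise ValueError(f"unknown strategy {strategy!r}")
    wm = kb.copy()
    materialize_types(wm, onto)
    tree = backward_chain(wm, onto, query, depth_limit)
    alternatives: dict = {}
    if strategy == "plausible" and not tree.complete:
        for _ in range(max_rounds):
            missing = [m for m in missing_premises(tree) if m.is_ground()]
            progressed = False
            for premise in missing:
                if _resolve_premise(wm, onto, plausible_rules, premise, decisions,
                                    config, alternatives, collect_alternatives):
                    progressed = True
            if not progressed:
                break
            tree = backward_chain(wm, onto, query, depth_limit)
            if tree.complete:
                break
    used_rules, used_facts = _plausible_items_in(tree)
    return QueryResult(
        query=query,
        answered=tree.complete,
        tree=tree,
        plausible_rules_used=used_rules,
        plausible_facts_used=used_facts,
        verification_state="verified" if decisions is not None else "unverified",
        alternatives=alternatives,
        working_memory=wm,
    )


def _resolve_premise(wm, onto, plausible_rules, premise, decisions, config,
                     alternatives, collect_alternatives) -> bool:
    """Try analogy then induction for one missing premise; returns progress."""
    target = str(premise.args[0].value)
    value = premise.args[1].value
    inferences = resolve_by_analogy(wm, onto, premise, plausible_rules)
    matching = [i for i in inferences
                if i.inferred.predicate == premise.predicate
                and i.inferred.value == value
                and (decisions is None or decisions.accepts_fact(i.inferred))]
    if matching:
        wm.add_fact(matching[0].inferred)
        if collect_alternatives:
            alternatives[str(premise)] = {
                "analogy": matching,
                "induction": induce_rules(wm, onto, premise, target, config),
            }
        return True
    candidates = induce_rules(wm, onto, premise, target, config)
    candidates = [c for c in candidates
                  if decisions is None or decisions.accepts_rule(c.rule)]
    if candidates:
        wm.assert_statement(candidates[0].rule, provenance="induction")
        if collect_alternatives:
            alternatives[str(premise)] = {"analogy": [], "induction": candidates}
        return True
    return False


def _plausible_items_in(tree: JustificationNode):
    """Plausible rules/facts actually appearing in the final justification."""
    rules, facts = [], []
    for node in tree.walk():
        if node.status == "plausible_induction" and node.rule_used is not None:
            if node.rule_used not in rules:
                rules.append(node.rule_used)
        elif node.status == "plausible_analogy" and node.literal.is_ground():
            fact = Fact(node.literal.predicate, str(node.literal.args[0].value),
                        node.literal.args[1].value, provenance="analogy")
            if fact not in facts:
                facts.append(fact)
    return rules, facts


def apply_verification(results: Sequence[QueryResult], decisions: DecisionFile,
                       kb: KnowledgeBase, onto: ConceptHierarchy,
                       plausible_rules: Sequence[PlausibleRule],
                       config: InductionConfig = InductionConfig()) -> List[QueryResult]:
    """Re-evaluate plausible-mode results under an expert's decisions and
    materialize accepted inferences into the shared KB.

    Results depending on any non-accepted rule or fact are recomputed in
    verified mode; some revert to unanswered (the coverage drop under
    verification).  Accepted items are asserted with their plausible
    provenance.
    """
    updated: List[QueryResult] = []
    for res in results:
        dependent = (any(not decisions.accepts_rule(r) for r in res.plausible_rules_used)
                     or any(not decisions.accepts_fact(f) for f in res.plausible_facts_used))
        if dependent:
            res = justify_query(kb, onto, plausible_rules, res.query,
                                strategy="plausible", decisions=decisions, config=config)
        else:
            res.verification_state = "verified"
        for rule in res.plausible_rules_used:
            if decisions.accepts_rule(rule):
                kb.assert_statement(rule, provenance="induction")
        for fact in res.plausible_facts_used:
            if decisions.accepts_fact(fact):
                kb.assert_statement(fact, provenance="analogy")
        updated.append(res)
    return updated
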