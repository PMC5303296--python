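"""Analogical reasoning: resolve a missing premise by transferring a feature
from a reference entity via a plausible rule.

A plausible rule "Q is plausibly determined by P" licenses the transfer: if
a *reference* entity holds both a condition-type feature P and a
consequent-type feature Q, and the *target* entity shares the same P value,
then the target plausibly holds Q as well.  The concept hierarchy widens
the search: a missing premise value is generalized along its ancestor
chain, nearest class first, when matching rule consequents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

from .model import Fact, KnowledgeBase, Literal, PlausibleRule
from .ontology import ConceptHierarchy


@dataclass(frozen=True)
class AnalogicalInference:
    """One licensed knowledge transfer, pending expert verification."""

    inferred: Fact
    rule: PlausibleRule
    reference_entity: str
    shared_value: str
    transferred_value: str
    support_count: int = 1


def candidate_plausible_rules(premise: Literal, rules: Sequence[PlausibleRule],
                              onto: ConceptHierarchy) -> List[PlausibleRule]:
    """Rules whose consequent matches the premise under value generalization.

    The premise value's full ancestor chain is searched nearest-first, so
    rules typed at a specific class are preferred over more general ones.
    """
    value = premise.args[1].value
    chain = onto.ancestor_chain(value)
    out: List[PlausibleRule] = []
    for cls in chain:
        for rule in rules:
            if rule in out:
                continue
            if rule.consequent.predicate == premise.predicate and rule.consequent_type == cls:
                out.append(rule)
    return out


def resolve_by_analogy(kb: KnowledgeBase, onto: ConceptHierarchy, premise: Literal,
                       rules: Sequence[PlausibleRule]) -> List[AnalogicalInference]:
    """All knowledge transfers resolving ``premise`` for its subject entity.

    For each candidate rule, reference entities unifying BOTH condition and
    consequent are located; a transfer is kept only when the instantiated
    condition also holds for the target.  Inferences never duplicate facts
    already in the KB (they fill gaps only) and are returned deterministically
    ordered by (rule order, reference entity); transfers of the same value are
    aggregated with a support count and ranked support-descending.
    """
    target = str(premise.args[0].value)
    found: dict = {}
    order: List[tuple] = []
    for r_idx, rule in enumerate(candidate_plausible_rules(premise, rules, onto)):
        cond_pred = rule.shared_condition.predicate
        cons_pred = rule.consequent.predicate
        target_cond = [v for v in kb.values_of(cond_pred, target)
                       if onto.is_instance_of(v, rule.condition_type, kb)]
        if not target_cond:
            continue
        for ref in kb.entities():
            if ref == target:
                continue
            shared = [v for v in target_cond if kb.holds(cond_pred, ref, v)]
            if not shared:
                continue
            transfers = [q for q in kb.values_of(cons_pred, ref)
                         if onto.is_instance_of(q, rule.consequent_type, kb)]
            for q in transfers:
                if kb.holds(cons_pred, target, q):
                    continue
                key = (r_idx, ref, q)
                if key in found:
                    continue
                fact = Fact(cons_pred, target, q, provenance="analogy",
                            supporting=(rule, ref, shared[0]))
                found[key] = AnalogicalInference(fact, rule, ref, shared[0], q)
                order.append(key)
    inferences = [found[k] for k in order]
    support = {}
    for inf in inferences:
        k = (inf.inferred.predicate, inf.transferred_value)
        support[k] = support.get(k, 0) + 1
    ranked = [AnalogicalInference(i.inferred, i.rule, i.reference_entity, i.shared_value,
                                  i.transferred_value,
                                  support[(i.inferred.predicate, i.transferred_value)])
              for i in inferences]
    ranked.sort(key=lambda i: (-i.support_count,
                               _rule_index(rules, i.rule), i.reference_entity))
    return ranked


def _rule_index(rules: Sequence[PlausibleRule], rule: PlausibleRule) -> int:
    for i, r in enumerate(rules):
        if r == rule:
            return i
    return len(rules)
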