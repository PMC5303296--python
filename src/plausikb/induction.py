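"""Inductive generalization: induce candidate deductive rules from the
commonalities among entities sharing a missing feature.

Given a missing premise ``feature(target, value)``, all other entities
holding the same feature are retrieved; the conditions each shares with the
target — exact predicate/value matches, or type-generalized matches
``predicate(_, (type L))`` when the differing values are conceptually
similar enough (Wu–Palmer similarity >= tau) — form candidate rule bodies.
Sharers with identical condition sets aggregate into one candidate rule,
ranked by positive coverage (entities satisfying body and head), body
length, then lexicographically.

Attributes irrelevant to the query (by default the patient's sex) are
blacklisted from rule bodies, and continuous attributes are excluded unless
equal-width binning is enabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .model import Const, DeductiveRule, KnowledgeBase, Literal, TypedVar, Var
from .ontology import ConceptHierarchy, OntologyError
from .unify import entity_satisfies

# Predicates that are bookkeeping or targets, never induction conditions.
_NON_FEATURE_PREDICATES = frozenset({"type", "live"})

DEFAULT_BLACKLIST = frozenset({"sex"})


@dataclass(frozen=True)
class InductionConfig:
    """Tunables for rule induction.

    tau: minimum Wu–Palmer similarity for type-generalizing differing values.
    min_coverage: minimum positive coverage for a candidate to be reported.
    blacklist: predicates excluded from rule bodies.
    bin_continuous: when set, numeric values enter bodies as equal-width bin
        labels over the observed range; by default numeric attributes are
        excluded entirely.
    """

    tau: float = 0.5
    min_coverage: int = 2
    blacklist: frozenset = DEFAULT_BLACKLIST
    bin_continuous: Optional[int] = None


@dataclass(frozen=True)
class GeneralizationStep:
    """Trace entry: which concrete values generalized to which class."""

    predicate: str
    values: tuple
    generalized_to: str
    similarity: float


@dataclass
class CandidateRule:
    rule: DeductiveRule
    positive_coverage: int
    supporting_entities: List[str]
    trace: List[GeneralizationStep] = field(default_factory=list)


def retrieve_sharing_entities(kb: KnowledgeBase, premise: Literal) -> List[str]:
    """Entities (other than the premise subject) holding the same feature."""
    target = str(premise.args[0].value)
    value = premise.args[1].value
    return sorted({f.subject for f in kb.facts_for(premise.predicate)
                   if f.value == value and f.subject != target})


def _feature_values(kb: KnowledgeBase, entity: str, config: InductionConfig,
                    ranges: Optional[dict] = None,
                    cache: Optional[dict] = None) -> Dict[str, set]:
    """Categorical (or binned) feature values per predicate for one entity."""
    if cache is not None:
        if not cache:
            cache.update(_all_feature_values(kb, config, ranges))
        return cache.get(entity, {})
    return _all_feature_values(kb, config, ranges).get(entity, {})


def _all_feature_values(kb: KnowledgeBase, config: InductionConfig,
                        ranges: Optional[dict]) -> Dict[str, Dict[str, set]]:
    """One pass over the KB: entity -> predicate -> categorical values."""
    out: Dict[str, Dict[str, set]] = {}
    for f in kb.facts():
        if f.predicate in _NON_FEATURE_PREDICATES or f.predicate in config.blacklist:
            continue
        if isinstance(f.value, (int, float)) and not isinstance(f.value, bool):
            if config.bin_continuous is None or not ranges:
                continue
            lo, hi = ranges.get(f.predicate, (None, None))
            if lo is None or hi <= lo:
                continue
            k = config.bin_continuous
            idx = min(int((f.value - lo) / (hi - lo) * k), k - 1)
            value = f"bin{idx}"
        else:
            value = f.value
        out.setdefault(f.subject, {}).setdefault(f.predicate, set()).add(value)
    return out


def _observed_ranges(kb: KnowledgeBase) -> dict:
    ranges: dict = {}
    for f in kb.facts():
        if isinstance(f.value, (int, float)) and not isinstance(f.value, bool):
            lo, hi = ranges.get(f.predicate, (math.inf, -math.inf))
            ranges[f.predicate] = (min(lo, f.value), max(hi, f.value))
    return ranges


def pairwise_shared_conditions(kb: KnowledgeBase, onto: ConceptHierarchy, target: str,
                               other: str, config: InductionConfig,
                               exclude: Tuple[str, object] = None,
                               ranges: Optional[dict] = None,
                               cache: Optional[dict] = None):
    """Conditions shared by ``target`` and ``other``.

    Per predicate: exact common values give ``pred(P, v)``; otherwise, if
    both hold values and the most similar pair reaches tau, the pair
    generalizes to ``pred(P, (type L))`` with L their least common subsumer.
    Returns (conditions, trace).
    """
    tv = _feature_values(kb, target, config, ranges, cache)
    ov = _feature_values(kb, other, config, ranges, cache)
    conditions: List[Literal] = []
    trace: List[GeneralizationStep] = []
    for pred in sorted(set(tv) & set(ov)):
        exact = tv[pred] & ov[pred]
        if exclude is not None and exclude[0] == pred:
            exact = exact - {exclude[1]}
        if exact:
            for v in sorted(exact, key=str):
                conditions.append(Literal(pred, (Var("P"), Const(v))))
            continue
        best: Optional[Tuple[float, str, tuple]] = None
        for a in sorted(tv[pred], key=str):
            for b in sorted(ov[pred], key=str):
                try:
                    sim = onto.consim(a, b)
                    lcs = onto.least_common_subsumer(a, b)
                except OntologyError:
                    continue
                if best is None or sim > best[0]:
                    best = (sim, lcs, (a, b))
        if best is not None and best[0] >= config.tau:
            conditions.append(Literal(pred, (Var("P"),
                                             TypedVar(f"_G_{pred}", best[1], anonymous=True))))
            trace.append(GeneralizationStep(pred, best[2], best[1], best[0]))
    return conditions, trace


def common_features(kb: KnowledgeBase, onto: ConceptHierarchy, entities: Sequence[str],
                    target: str, config: InductionConfig = InductionConfig(),
                    exclude: Tuple[str, object] = None) -> List[Literal]:
    """Conditions held by ALL given entities and the target (exact or
    type-generalized), blacklist applied."""
    ranges = _observed_ranges(kb) if config.bin_continuous else None
    cache: dict = {}
    shared: Optional[set] = None
    for e in entities:
        conds, _ = pairwise_shared_conditions(kb, onto, target, e, config, exclude, ranges,
                                              cache)
        cset = set(conds)
        shared = cset if shared is None else (shared & cset)
        if not shared:
            break
    return sorted(shared or (), key=str)


def _coverage(kb: KnowledgeBase, onto: ConceptHierarchy, head: Literal,
              body: Sequence[Literal]) -> List[str]:
    """Entities satisfying both body and head, recomputable via match_facts."""
    value = head.args[1].value
    holders = sorted({f.subject for f in kb.facts_for(head.predicate) if f.value == value})
    return [e for e in holders if entity_satisfies(kb, onto, e, body)]


def induce_rules(kb: KnowledgeBase, onto: ConceptHierarchy, premise: Literal,
                 target: Optional[str] = None,
                 config: InductionConfig = InductionConfig()) -> List[CandidateRule]:
    """Induce candidate deductive rules for a missing ``premise``.

    The head is the premise generalized over its subject; each body is the
    set of conditions one group of sharing entities has in common with the
    target.  Candidates below ``min_coverage`` are dropped; the target
    satisfies every returned body by construction.
    """
    target = target or str(premise.args[0].value)
    value = premise.args[1].value
    head = Literal(premise.predicate, (Var("P"), Const(value)))
    sharers = retrieve_sharing_entities(kb, premise)
    if not sharers:
        return []
    ranges = _observed_ranges(kb) if config.bin_continuous else None
    cache: dict = {}
    groups: Dict[frozenset, dict] = {}
    for s in sharers:
        conds, trace = pairwise_shared_conditions(
            kb, onto, target, s, config, exclude=(premise.predicate, value), ranges=ranges,
            cache=cache)
        if not conds:
            continue
        key = frozenset(conds)
        g = groups.setdefault(key, {"body": sorted(conds, key=str), "trace": trace,
                                    "sharers": []})
        g["sharers"].append(s)
    out: List[CandidateRule] = []
    for g in groups.values():
        body = g["body"]
        supporting = _coverage(kb, onto, head, body)
        if len(supporting) < config.min_coverage:
            continue
        rule = DeductiveRule(head, tuple(body), provenance="induction")
        out.append(CandidateRule(rule, len(supporting), supporting, g["trace"]))
    out.sort(key=lambda c: (-c.positive_coverage, len(c.rule.body), str(c.rule)))
    return out
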