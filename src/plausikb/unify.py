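"""Unification, fact matching and built-in comparison predicates."""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional

from .model import Const, Fact, KnowledgeBase, Literal, TypedVar, Var
from .ontology import ConceptHierarchy, OntologyError

Bindings = Dict[str, object]

# Comparison predicates evaluated on bound scalars, never matched against facts.
BUILTIN_PREDICATES = {
    "lessThan": lambda a, b: a < b,
    "lessThanOrEqual": lambda a, b: a <= b,
    "greaterThan": lambda a, b: a > b,
    "greaterThanOrEqual": lambda a, b: a >= b,
    "notEqual": lambda a, b: a != b,
    "between": lambda a, lo, hi: lo <= a <= hi,
}


def is_builtin(predicate: str) -> bool:
    return predicate in BUILTIN_PREDICATES


def substitute(literal: Literal, bindings: Bindings) -> Literal:
    args = []
    for a in literal.args:
        if isinstance(a, (Var, TypedVar)) and a.name in bindings:
            args.append(Const(bindings[a.name]))
        else:
            args.append(a)
    return Literal(literal.predicate, tuple(args))


def eval_builtin(literal: Literal, bindings: Optional[Bindings] = None) -> Optional[bool]:
    """Evaluate a ground builtin; returns None if any argument is unbound."""
    g = substitute(literal, bindings or {})
    if not g.is_ground():
        return None
    values = [a.value for a in g.args]
    try:
        return bool(BUILTIN_PREDICATES[g.predicate](*values))
    except TypeError:
        return False


def _term_matches(term, value, bindings: Bindings, onto: Optional[ConceptHierarchy],
                  kb: Optional[KnowledgeBase]) -> Optional[Bindings]:
    """Match one pattern term against a ground value; returns extended bindings."""
    if isinstance(term, Const):
        return bindings if term.value == value else None
    if term.name in bindings:
        return bindings if bindings[term.name] == value else None
    if isinstance(term, TypedVar):
        if onto is None:
            raise OntologyError("type constraint requires an ontology")
        if not onto.is_instance_of(value, term.cls, kb):
            return None
    out = dict(bindings)
    out[term.name] = value
    return out


def match_fact(pattern: Literal, fact: Fact, bindings: Bindings,
               onto: Optional[ConceptHierarchy], kb: Optional[KnowledgeBase]) -> Optional[Bindings]:
    if pattern.predicate != fact.predicate or len(pattern.args) != 2:
        return None
    b = _term_matches(pattern.args[0], fact.subject, bindings, onto, kb)
    if b is None:
        return None
    return _term_matches(pattern.args[1], fact.value, b, onto, kb)


_PROVENANCE_ORDER = {"asserted": 0, "ontology": 1, "analogy": 2, "induction": 3}


def match_facts(kb: KnowledgeBase, pattern: Literal,
                onto: Optional[ConceptHierarchy] = None,
                bindings: Optional[Bindings] = None) -> List[Bindings]:
    """All bindings instantiating ``pattern`` to a fact (asserted or inferred).

    Type constraints admit instances of the named class or any subclass.
    Builtin patterns are evaluated, not matched: a true ground builtin yields
    the single trivial binding.  Deterministic order: asserted facts before
    inferred ones, then by (subject, value).
    """
    bindings = bindings or {}
    if is_builtin(pattern.predicate):
        result = eval_builtin(pattern, bindings)
        return [dict(bindings)] if result else []
    out = []
    subj = pattern.args[0]
    if isinstance(subj, Const):
        candidates = kb.facts_for_subject(pattern.predicate, subj.value)
    elif subj.name in bindings:
        candidates = kb.facts_for_subject(pattern.predicate, bindings[subj.name])
    else:
        candidates = kb.facts_for(pattern.predicate)
    facts = sorted(candidates,
                   key=lambda f: (_PROVENANCE_ORDER[f.provenance], str(f.subject), str(f.value)))
    for fact in facts:
        b = match_fact(pattern, fact, bindings, onto, kb)
        if b is not None:
            out.append(b)
    return out


def match_body(kb: KnowledgeBase, body: Iterable[Literal],
               onto: Optional[ConceptHierarchy] = None,
               bindings: Optional[Bindings] = None) -> List[Bindings]:
    """Conjunctive match of a rule body; all satisfying bindings, in order."""
    solutions = [dict(bindings or {})]
    for literal in body:
        nxt = []
        for b in solutions:
            nxt.extend(match_facts(kb, literal, onto, b))
        solutions = nxt
        if not solutions:
            break
    return solutions


def entity_satisfies(kb: KnowledgeBase, onto: Optional[ConceptHierarchy],
                     entity: str, body: Iterable[Literal], entity_var: str = "P") -> bool:
    """Does ``entity``, bound to ``entity_var``, satisfy every body literal?"""
    return bool(match_body(kb, body, onto, {entity_var: entity}))
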