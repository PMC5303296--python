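"""Independent brute-force oracles used to cross-check the engine.

These deliberately avoid the package's unification/matching machinery:
facts are plain (predicate, subject, value) triples and matching is done
with nested loops, so agreement with the engine is a real check.
"""

from plausikb.model import Const


def _term_value(term, binding):
    if isinstance(term, Const):
        return term.value
    return binding.get(term.name)


def _match_literal(literal, triple, binding):
    """Extend binding so that literal == triple, or return None."""
    pred, subj, val = triple
    if literal.predicate != pred:
        return None
    out = dict(binding)
    for term, ground in zip(literal.args, (subj, val)):
        if isinstance(term, Const):
            if term.value != ground:
                return None
        else:
            if term.name in out:
                if out[term.name] != ground:
                    return None
            else:
                out[term.name] = ground
    return out


def enumerate_bindings(body, triples, binding=None):
    """All substitutions grounding every body literal in the triple set."""
    solutions = [binding or {}]
    for literal in body:
        nxt = []
        for b in solutions:
            for triple in triples:
                b2 = _match_literal(literal, triple, b)
                if b2 is not None:
                    nxt.append(b2)
        solutions = nxt
    return solutions


def forward_closure(triples, rules, max_rounds=100):
    """Naive forward chaining to fixpoint over (pred, subj, val) triples."""
    derived = set(triples)
    for _ in range(max_rounds):
        added = False
        for rule in rules:
            for b in enumerate_bindings(rule.body, sorted(derived)):
                head = (rule.head.predicate,
                        _term_value(rule.head.args[0], b),
                        _term_value(rule.head.args[1], b))
                if None not in head and head not in derived:
                    derived.add(head)
                    added = True
        if not added:
            return derived
    raise AssertionError("forward chaining did not reach a fixpoint")
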