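"""Backward-chaining prover producing justification trees.

A justification tree records *why* a query holds — or exactly where it
fails.  Leaves are KB facts, ontology inferences, plausible inferences or
explicitly ``missing`` premises; internal nodes record the deductive rule
applied.  A tree is *complete* when no descendant is missing; missing
leaves are the triggers for analogical and inductive gap-filling.

Resolution order per premise: matching fact (asserted before inferred),
then rules in file order; the first complete proof is kept.  When no
complete proof exists, a single best-effort tree is built (rule with the
fewest missing leaves; ties by file order) so that every unproven premise
is exposed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

from .model import Const, DeductiveRule, KnowledgeBase, Literal, TypedVar, Var
from .ontology import ConceptHierarchy
from .unify import Bindings, eval_builtin, is_builtin, match_fact, substitute

_FACT_STATUS = {
    "asserted": "fact",
    "ontology": "ontology_inferred",
    "analogy": "plausible_analogy",
    "induction": "plausible_induction",
}

STATUSES = ("fact", "ontology_inferred", "rule_derived",
            "plausible_analogy", "plausible_induction", "missing")


def _display(literal: Literal) -> Literal:
    """Strip internal standardize-apart suffixes from variable names."""
    args = []
    for a in literal.args:
        if isinstance(a, Var):
            args.append(Var(a.name.split("__", 1)[0]))
        elif isinstance(a, TypedVar):
            args.append(TypedVar(a.name.split("__", 1)[0], a.cls, a.anonymous))
        else:
            args.append(a)
    return Literal(literal.predicate, tuple(args))


@dataclass
class JustificationNode:
    literal: Literal
    status: str
    rule_used: Optional[DeductiveRule] = None
    children: List["JustificationNode"] = field(default_factory=list)
    note: Optional[str] = None

    @property
    def complete(self) -> bool:
        return self.status != "missing" and all(c.complete for c in self.children)

    def walk(self) -> Iterator["JustificationNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def to_dict(self) -> dict:
        d = {"literal": str(self.literal), "status": self.status}
        if self.rule_used is not None:
            d["rule"] = str(self.rule_used)
        if self.note:
            d["note"] = self.note
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=kwargs.pop("indent", 2), **kwargs)

    def to_text(self, _depth: int = 0) -> str:
        """Indented rendering of the proof (textual stand-in for a tree view)."""
        marker = {"fact": "[fact]", "ontology_inferred": "[ontology]",
                  "rule_derived": "[rule]", "plausible_analogy": "[analogy]",
                  "plausible_induction": "[induction]", "missing": "[MISSING]"}[self.status]
        line = "  " * _depth + f"{self.literal}  {marker}"
        if self.note:
            line += f"  ({self.note})"
        return "\n".join([line] + [c.to_text(_depth + 1) for c in self.children])


JustificationTree = JustificationNode


def missing_premises(tree: JustificationNode) -> List[Literal]:
    """Depth-first, left-to-right list of missing leaves; empty iff complete."""
    return [n.literal for n in tree.walk() if n.status == "missing"]


# ---------------------------------------------------------------------------
# Prover
# ---------------------------------------------------------------------------

class _Prover:
    def __init__(self, kb: KnowledgeBase, onto: Optional[ConceptHierarchy], depth_limit: int):
        self.kb = kb
        self.onto = onto
        self.depth_limit = depth_limit
        self._rename = itertools.count(1)

    # -- complete proof search (SLD with backtracking) --------------------

    def prove_complete(self, goal: Literal, bindings: Bindings, depth: int,
                       visited: frozenset) -> Iterator[Tuple[JustificationNode, Bindings]]:
        g = substitute(goal, bindings)
        if is_builtin(g.predicate):
            if eval_builtin(g):
                yield JustificationNode(_display(g), "fact", note="builtin"), bindings
            return
        for fact in self._facts_for(g):
            b = match_fact(g, fact, bindings, self.onto, self.kb)
            if b is not None:
                node = JustificationNode(_display(substitute(g, b)), _FACT_STATUS[fact.provenance])
                yield node, b
        sig = str(g)
        if depth <= 0 or sig in visited:
            return
        for rule in self.kb.deductive_rules:
            head, body = self._standardize(rule)
            b = self._unify_head(head, g, bindings)
            if b is None:
                continue
            for children, b2 in self._prove_body_complete(body, b, depth - 1, visited | {sig}):
                yield JustificationNode(_display(substitute(g, b2)), self._rule_status(rule),
                                        rule_used=rule, children=children), b2

    def _prove_body_complete(self, body, bindings, depth, visited):
        if not body:
            yield [], bindings
            return
        first, rest = body[0], body[1:]
        for node, b in self.prove_complete(first, bindings, depth, visited):
            for nodes, b2 in self._prove_body_complete(rest, b, depth, visited):
                yield [node] + nodes, b2

    # -- best-effort tree --------------------------------------------------

    def prove_best(self, goal: Literal, bindings: Bindings, depth: int,
                   visited: frozenset) -> Tuple[JustificationNode, Bindings]:
        for node, b in self.prove_complete(goal, bindings, depth, visited):
            return node, b
        g = substitute(goal, bindings)
        if is_builtin(g.predicate):
            # Builtins are evaluated, never "missing": when the underlying
            # scalar premise is absent the scalar literal is the missing leaf.
            return JustificationNode(_display(g), "fact", note="builtin not evaluated (unbound)"), bindings
        sig = str(g)
        if depth <= 0 or sig in visited:
            note = "depth limit exceeded" if depth <= 0 else "cycle detected"
            return JustificationNode(_display(g), "missing", note=note), bindings
        candidates = []
        for order, rule in enumerate(self.kb.deductive_rules):
            head, body = self._standardize(rule)
            b = self._unify_head(head, g, bindings)
            if b is None:
                continue
            children: List[JustificationNode] = []
            failed = False
            for literal in body:
                if is_builtin(literal.predicate):
                    result = eval_builtin(literal, b)
                    if result is False:
                        failed = True
                        break
                child, b = self.prove_best(literal, b, depth - 1, visited | {sig})
                children.append(child)
            if failed:
                continue
            node = JustificationNode(_display(substitute(g, b)), self._rule_status(rule),
                                     rule_used=rule, children=children)
            n_missing = sum(1 for n in node.walk() if n.status == "missing")
            candidates.append((n_missing, order, node))
        if not candidates:
            return JustificationNode(_display(g), "missing"), bindings
        candidates.sort(key=lambda t: (t[0], t[1]))
        return candidates[0][2], bindings

    # -- helpers -----------------------------------------------------------

    def _facts_for(self, g: Literal):
        order = {"asserted": 0, "ontology": 1, "analogy": 2, "induction": 3}
        return sorted(self.kb.facts_for(g.predicate),
                      key=lambda f: (order[f.provenance], str(f.subject), str(f.value)))

    @staticmethod
    def _rule_status(rule: DeductiveRule) -> str:
        return "plausible_induction" if rule.provenance == "induction" else "rule_derived"

    def _standardize(self, rule: DeductiveRule):
        """Rename rule variables apart from the caller's."""
        suffix = f"__{next(self._rename)}"

        def ren(literal: Literal) -> Literal:
            args = []
            for a in literal.args:
                if isinstance(a, Var):
                    args.append(Var(a.name + suffix))
                elif isinstance(a, TypedVar):
                    args.append(TypedVar(a.name + suffix, a.cls, a.anonymous))
                else:
                    args.append(a)
            return Literal(literal.predicate, tuple(args))

        return ren(rule.head), tuple(ren(b) for b in rule.body)

    def _unify_head(self, head: Literal, goal: Literal, bindings: Bindings) -> Optional[Bindings]:
        """Unify a renamed rule head with a (possibly partially ground) goal."""
        if head.predicate != goal.predicate or len(head.args) != len(goal.args):
            return None
        b = dict(bindings)
        for h, g in zip(head.args, goal.args):
            g = substitute(Literal("x", (g,)), b).args[0]
            if isinstance(g, Const):
                if isinstance(h, Const):
                    if h.value != g.value:
                        return None
                else:
                    if isinstance(h, TypedVar) and self.onto is not None:
                        if not self.onto.is_instance_of(g.value, h.cls, self.kb):
                            return None
                    if h.name in b and b[h.name] != g.value:
                        return None
                    b[h.name] = g.value
            else:
                # goal arg is an unbound variable: link it to the head term
                if isinstance(h, Const):
                    b[g.name] = h.value
                # var-var links are resolved lazily: leave both unbound
        return b


def backward_chain(kb: KnowledgeBase, onto: Optional[ConceptHierarchy], query: Literal,
                   depth_limit: int = 25) -> JustificationNode:
    """Prove ``query`` (entity arguments ground) against facts and rules.

    Returns a justification tree; unresolvable premises appear as
    ``missing`` leaves rather than raising.  Deterministic given rule order.
    """
    prover = _Prover(kb, onto, depth_limit)
    node, _ = prover.prove_best(query, {}, depth_limit, frozenset())
    return node
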