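"""Core data model: terms, literals, facts, rules and the knowledge base.

The knowledge base stores ground binary facts ``predicate(subject, value)``
partitioned by provenance.  Facts asserted from source data are immutable
under reasoning; facts contributed by ontology materialization, analogical
transfer or induced rules are retractable, giving the engine its
non-monotonic contract: retracting all inferred knowledge restores the
asserted state exactly.

Negative observations are encoded as distinct predicates carrying a ``no``
prefix (``noPhysicalSign``, ``noSymptom``, ...).  Absence of both the
positive and the negative fact means the attribute is *missing* — never
false (open world).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Union

PROVENANCES = ("asserted", "ontology", "analogy", "induction")

Value = Union[str, int, float]


class KBError(Exception):
    """Raised on contract violations in knowledge-base operations."""


# ---------------------------------------------------------------------------
# Terms and literals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Var:
    """A logic variable (dialect: one upper-case letter plus optional digits)."""

    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Const:
    """A ground constant: entity id, concept instance, or numeric scalar."""

    value: Value

    def __str__(self) -> str:
        return _format_value(self.value)


@dataclass(frozen=True)
class TypedVar:
    """A variable restricted to instances of an ontology class.

    Written ``(type Antiviral) M`` in the rule dialect, or bare
    ``(type Antiviral)`` for an anonymous typed variable.
    """

    name: str
    cls: str
    anonymous: bool = False

    def __str__(self) -> str:
        if self.anonymous:
            return f"(type {self.cls})"
        return f"(type {self.cls}) {self.name}"


Term = Union[Var, Const, TypedVar]


def _format_value(v: Value) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


@dataclass(frozen=True)
class Literal:
    """A predicate applied to terms; ground when every argument is a Const."""

    predicate: str
    args: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "args", tuple(self.args))

    @property
    def type_constraints(self) -> dict:
        """Map variable name -> required ontology class, from typed arguments."""
        return {a.name: a.cls for a in self.args if isinstance(a, TypedVar)}

    def is_ground(self) -> bool:
        return all(isinstance(a, Const) for a in self.args)

    def variables(self) -> set:
        return {a.name for a in self.args if isinstance(a, (Var, TypedVar))}

    def __str__(self) -> str:
        return f"{self.predicate}({', '.join(str(a) for a in self.args)})"


def lit(predicate: str, *args: object) -> Literal:
    """Convenience constructor: plain python values become Const terms."""
    terms = tuple(a if isinstance(a, (Var, Const, TypedVar)) else Const(a) for a in args)
    return Literal(predicate, terms)


# ---------------------------------------------------------------------------
# Facts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fact:
    """A ground ``predicate(subject, value)`` statement.

    Equality and hashing consider only the triple, so a fact cannot coexist
    in two provenance partitions; ``provenance`` records how it entered the
    KB and ``supporting`` the rule / reference entity that produced it.
    ``attribute`` tags facts originating from a named cohort attribute
    (the unit of missing-data accounting).
    """

    predicate: str
    subject: str
    value: Value
    provenance: str = field(default="asserted", compare=False)
    supporting: object = field(default=None, compare=False, repr=False)
    attribute: Optional[str] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise KBError(f"unknown provenance {self.provenance!r}")

    @property
    def key(self) -> tuple:
        return (self.predicate, self.subject, self.value)

    def to_literal(self) -> Literal:
        return Literal(self.predicate, (Const(self.subject), Const(self.value)))

    def __str__(self) -> str:
        return f"{self.predicate}({self.subject}, {_format_value(self.value)})"


def fingerprint_fact(fact: Fact) -> str:
    """Canonical whitespace-free serialization used in decision files."""
    return f"{fact.predicate}({fact.subject},{_format_value(fact.value)})"


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeductiveRule:
    """Horn rule ``head :- body`` over binary literals and builtins."""

    head: Literal
    body: tuple
    provenance: str = field(default="asserted", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "body", tuple(self.body))
        if not self.body:
            raise KBError("deductive rule requires a non-empty body")
        bound = set()
        for b in self.body:
            bound |= b.variables()
        unbound = self.head.variables() - bound - set(self.head.type_constraints)
        if unbound:
            raise KBError(f"head variables {sorted(unbound)} not bound by body or type constraint")

    def __str__(self) -> str:
        return f"{self.head} :- {', '.join(str(b) for b in self.body)}."


@dataclass(frozen=True)
class PlausibleRule:
    """"Q is plausibly determined by P": entities sharing a feature of the
    condition type plausibly share a feature of the consequent type.

    Dialect: ``consequent_template <~ condition_template .`` where both
    templates mention the same entity variable and a typed value variable,
    e.g. ``physicalSign(X, (type LiverIssue) L) <~ physicalSign(X, (type VeinIssue) V).``
    """

    consequent: Literal
    shared_condition: Literal

    def __post_init__(self) -> None:
        ent_c = _entity_var(self.shared_condition)
        ent_q = _entity_var(self.consequent)
        if ent_c != ent_q:
            raise KBError("plausible rule condition and consequent must share the entity variable")
        if self.condition_type is None or self.consequent_type is None:
            raise KBError("plausible rule requires typed value variables on both sides")

    @property
    def condition_type(self) -> Optional[str]:
        return _value_type(self.shared_condition)

    @property
    def consequent_type(self) -> Optional[str]:
        return _value_type(self.consequent)

    def __str__(self) -> str:
        return f"{self.consequent} <~ {self.shared_condition}."


def _entity_var(template: Literal) -> Optional[str]:
    a = template.args[0]
    return a.name if isinstance(a, Var) else None


def _value_type(template: Literal) -> Optional[str]:
    a = template.args[1]
    return a.cls if isinstance(a, TypedVar) else None


def fingerprint_rule(rule: Union[DeductiveRule, PlausibleRule]) -> str:
    return str(rule).replace(" ", "")


# ---------------------------------------------------------------------------
# Knowledge base
# ---------------------------------------------------------------------------

class KnowledgeBase:
    """Fact and rule store with provenance partitions and set semantics."""

    def __init__(self, ontology=None):
        self._facts: dict = {}          # key -> Fact
        self._by_pred: dict = {}        # predicate -> dict key -> Fact
        self._by_pred_subj: dict = {}   # (predicate, subject) -> dict key -> Fact
        self.deductive_rules: list = []
        self.plausible_rules: list = []
        self.ontology = ontology
        self._frozen = False

    # -- fact access ------------------------------------------------------

    def __len__(self) -> int:
        return len(self._facts)

    def __contains__(self, fact: Fact) -> bool:
        return fact.key in self._facts

    def facts(self) -> Iterator[Fact]:
        return iter(self._facts.values())

    @property
    def asserted(self) -> list:
        return [f for f in self._facts.values() if f.provenance == "asserted"]

    @property
    def inferred(self) -> list:
        return [f for f in self._facts.values() if f.provenance != "asserted"]

    def facts_for(self, predicate: str) -> list:
        return list(self._by_pred.get(predicate, {}).values())

    def facts_for_subject(self, predicate: str, subject: str) -> list:
        return list(self._by_pred_subj.get((predicate, subject), {}).values())

    def holds(self, predicate: str, subject: str, value: Value) -> bool:
        return (predicate, subject, value) in self._facts

    def get(self, predicate: str, subject: str, value: Value) -> Optional[Fact]:
        return self._facts.get((predicate, subject, value))

    def values_of(self, predicate: str, subject: str) -> list:
        return sorted((f.value for f in self.facts_for_subject(predicate, subject)), key=str)

    def entities(self) -> list:
        """Subjects of all facts, sorted."""
        return sorted({f.subject for f in self._facts.values()})

    # -- mutation ---------------------------------------------------------

    def freeze(self) -> None:
        """Disallow further asserted-provenance additions (reasoning may proceed)."""
        self._frozen = True

    def add_fact(self, fact: Fact) -> bool:
        """Insert under set semantics; returns False if the triple already exists."""
        if fact.provenance == "asserted" and self._frozen:
            raise KBError("knowledge base is frozen: cannot assert new ground truth")
        if fact.key in self._facts:
            return False
        self._facts[fact.key] = fact
        self._by_pred.setdefault(fact.predicate, {})[fact.key] = fact
        self._by_pred_subj.setdefault((fact.predicate, fact.subject), {})[fact.key] = fact
        return True

    def add_rule(self, rule: Union[DeductiveRule, PlausibleRule]) -> bool:
        if isinstance(rule, PlausibleRule):
            if rule in self.plausible_rules:
                return False
            self.plausible_rules.append(rule)
            return True
        if rule in self.deductive_rules:
            return False
        self.deductive_rules.append(rule)
        return True

    def assert_statement(self, item, provenance: str = "asserted") -> bool:
        """Store a fact or rule under the given provenance partition (idempotent)."""
        if isinstance(item, Fact):
            return self.add_fact(replace(item, provenance=provenance))
        if isinstance(item, DeductiveRule):
            return self.add_rule(replace(item, provenance=provenance))
        if isinstance(item, PlausibleRule):
            return self.add_rule(item)
        raise KBError(f"cannot assert object of type {type(item).__name__}")

    def retract_fact(self, fact: Fact) -> bool:
        existing = self._facts.pop(fact.key, None)
        if existing is None:
            return False
        del self._by_pred[existing.predicate][existing.key]
        del self._by_pred_subj[(existing.predicate, existing.subject)][existing.key]
        return True

    def retract_inferred(self) -> int:
        """Drop every inferred fact and induced rule; restores the asserted state."""
        removed = [f for f in self._facts.values() if f.provenance != "asserted"]
        for f in removed:
            self.retract_fact(f)
        n_rules = len(self.deductive_rules)
        self.deductive_rules = [r for r in self.deductive_rules if r.provenance == "asserted"]
        return len(removed) + (n_rules - len(self.deductive_rules))

    def copy(self) -> "KnowledgeBase":
        """Independent fact/rule stores sharing the (immutable) fact objects."""
        kb = KnowledgeBase(ontology=self.ontology)
        kb._facts = dict(self._facts)
        kb._by_pred = {p: dict(d) for p, d in self._by_pred.items()}
        kb._by_pred_subj = {k: dict(d) for k, d in self._by_pred_subj.items()}
        kb.deductive_rules = list(self.deductive_rules)
        kb.plausible_rules = list(self.plausible_rules)
        return kb
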