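"""Knowledge-base and ontology I/O.

Two on-disk formats are supported for fact stores:

* a Turtle subset (``.ttl``) in a single default namespace: ``:p116
  :physicalSign :varices .`` and ``:p116 a :Patient .``; numeric values are
  plain literals.
* a predicate-text format (any other extension): one ground literal per
  line, ``physicalSign(p116, varices).``

Ontologies use the same Turtle subset with ``rdfs:subClassOf`` for the class
DAG, ``rdf:type`` for instance assertions, and a small definition vocabulary
(``:onProperty`` / ``:someValuesFrom`` on a class that is also a
``rdfs:subClassOf`` of its required superclass) for existential class
definitions.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import rdflib
from rdflib import Graph, Namespace, URIRef
from rdflib.namespace import RDF, RDFS

from .model import Fact, KBError, KnowledgeBase
from .ontology import ClassDefinition, ConceptHierarchy
from .ruleio import parse_literal_text

logger = logging.getLogger(__name__)

NS = Namespace("http://example.org/hep#")


def _local(term) -> object:
    if isinstance(term, URIRef):
        return str(term).rsplit("#", 1)[-1].rsplit("/", 1)[-1]
    value = term.toPython()
    if isinstance(value, bool):
        return "true" if value else "false"
    return value


def _value_node(value):
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return rdflib.Literal(value)
    return NS[str(value)]


# ---------------------------------------------------------------------------
# Fact stores
# ---------------------------------------------------------------------------

def load_kb(path, ontology: Optional[ConceptHierarchy] = None,
            known_predicates: Optional[set] = None, strict: bool = False) -> KnowledgeBase:
    """Load a fact store; every statement becomes a provenance=asserted Fact.

    ``known_predicates`` restricts the vocabulary: unknown predicates are
    fatal when ``strict`` else reported and skipped.  Loading is idempotent
    under set semantics.
    """
    path = Path(path)
    kb = KnowledgeBase(ontology=ontology)
    if path.suffix == ".ttl":
        facts = _facts_from_turtle(path)
    else:
        facts = _facts_from_text(path)
    for fact in facts:
        if known_predicates is not None and fact.predicate not in known_predicates:
            if strict:
                raise KBError(f"unknown predicate {fact.predicate!r} in {path}")
            logger.warning("skipping fact with unknown predicate: %s", fact)
            continue
        kb.add_fact(fact)
    return kb


def _facts_from_turtle(path: Path) -> Iterable[Fact]:
    g = Graph()
    g.parse(path, format="turtle")
    for s, p, o in sorted(g):
        subject = str(_local(s))
        if p == RDF.type:
            yield Fact("type", subject, str(_local(o)))
        else:
            yield Fact(str(_local(p)), subject, _local(o))


def _facts_from_text(path: Path) -> Iterable[Fact]:
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("%", "#")):
            continue
        literal = parse_literal_text(line)
        if not literal.is_ground() or len(literal.args) != 2:
            raise KBError(f"{path}:{lineno}: facts must be ground binary literals: {line!r}")
        yield Fact(literal.predicate, str(literal.args[0].value), literal.args[1].value)


def save_kb_turtle(kb: KnowledgeBase, path, asserted_only: bool = True) -> None:
    g = Graph()
    g.bind("", NS)
    facts = kb.asserted if asserted_only else list(kb.facts())
    for f in facts:
        s = NS[f.subject]
        if f.predicate == "type":
            g.add((s, RDF.type, NS[str(f.value)]))
        else:
            g.add((s, NS[f.predicate], _value_node(f.value)))
    Path(path).write_text(g.serialize(format="turtle"))


def save_kb_text(kb: KnowledgeBase, path, asserted_only: bool = True) -> None:
    facts = kb.asserted if asserted_only else list(kb.facts())
    lines = sorted(f"{f}." for f in facts)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ontologies
# ---------------------------------------------------------------------------

ONPROPERTY = NS["onProperty"]
SOMEVALUES = NS["someValuesFrom"]


def load_ontology(path) -> ConceptHierarchy:
    g = Graph()
    g.parse(Path(path), format="turtle")
    onto = ConceptHierarchy()
    for s, o in sorted(g.subject_objects(RDFS.subClassOf)):
        onto.add_class(str(_local(s)), str(_local(o)))
    for s, o in sorted(g.subject_objects(RDF.type)):
        cls = str(_local(o))
        inst = str(_local(s))
        if cls in ("Class", "Ontology"):
            continue
        if onto.has_class(inst):
            continue
        onto.add_instance(inst, cls)
    for s in sorted(set(g.subjects(ONPROPERTY))):
        prop = str(_local(next(g.objects(s, ONPROPERTY))))
        filler = str(_local(next(g.objects(s, SOMEVALUES))))
        supers = [str(_local(o)) for o in g.objects(s, RDFS.subClassOf)]
        if not supers:
            raise KBError(f"defined class {_local(s)} lacks rdfs:subClassOf")
        onto.add_definition(ClassDefinition(str(_local(s)), sorted(supers)[0], prop, filler))
    onto.validate()
    return onto


def save_ontology(onto: ConceptHierarchy, path) -> None:
    g = Graph()
    g.bind("", NS)
    g.bind("rdfs", RDFS)
    for cls in sorted(onto.classes):
        for parent in onto.parents(cls):
            g.add((NS[cls], RDFS.subClassOf, NS[parent]))
    for inst, classes in sorted(onto.instances.items()):
        for cls in sorted(classes):
            g.add((NS[inst], RDF.type, NS[cls]))
    for d in onto.definitions:
        g.add((NS[d.defined_class], RDFS.subClassOf, NS[d.required_superclass]))
        g.add((NS[d.defined_class], ONPROPERTY, NS[d.property]))
        g.add((NS[d.defined_class], SOMEVALUES, NS[d.filler_class]))
    Path(path).write_text(g.serialize(format="turtle"))
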