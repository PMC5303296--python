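"""Concept hierarchy, existential class definitions, type materialization,
least common subsumer and Wu–Palmer conceptual similarity.

The hierarchy is a rooted DAG of classes (child -> parent edges) plus
instance-of links for concept instances (``varices``, ``Lamivudine``, ...)
and a list of existential class definitions of the form::

    Defined  ==  RequiredSuperclass  AND  EXISTS property . FillerClass

Conceptual similarity (ConSim) is the Wu–Palmer measure::

    ConSim(C1, C2) = 2*N3 / (N1 + N2 + 2*N3)

with C3 the deepest common subsumer, N1/N2 the edge counts from C1/C2 up to
C3, and N3 the edge count (depth) from C3 up to the root.  Named instances
count as leaf nodes one edge below their most specific asserted class, so
two distinct antivirals score 2d/(2 + 2d) < 1 while identical arguments
score exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .model import Fact, KBError, KnowledgeBase

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassDefinition:
    """Existential definition: ``defined_class == required_superclass AND
    EXISTS property.filler_class``."""

    defined_class: str
    required_superclass: str
    property: str
    filler_class: str


@dataclass(frozen=True)
class SimilarityCounts:
    """Edge counts behind one ConSim evaluation."""

    n1: int
    n2: int
    n3: int
    c3: str


class OntologyError(KBError):
    pass


class ConceptHierarchy:
    """Rooted class DAG with instance typing and existential definitions."""

    def __init__(self):
        self._g = nx.DiGraph()            # edges child -> parent
        self.instances: dict = {}         # instance -> set of asserted classes
        self.definitions: list = []
        self._depth_cache = None
        self._sim_cache: dict = {}

    # -- construction -----------------------------------------------------

    def add_class(self, name: str, parent: Optional[str] = None) -> None:
        self._g.add_node(name)
        if parent is not None:
            self._g.add_node(parent)
            self._g.add_edge(name, parent)
        self._invalidate()

    def add_instance(self, name: str, cls: str) -> None:
        if cls not in self._g:
            raise OntologyError(f"instance {name!r} asserted to unknown class {cls!r}")
        self.instances.setdefault(name, set()).add(cls)
        self._sim_cache = {}

    def add_definition(self, definition: ClassDefinition) -> None:
        for c in (definition.defined_class, definition.required_superclass,
                  definition.filler_class):
            if c not in self._g:
                raise OntologyError(f"class definition references unknown class {c!r}")
        if definition not in self.definitions:
            self.definitions.append(definition)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self._g):
            raise OntologyError("subclass cycle detected")
        roots = [n for n in self._g if self._g.out_degree(n) == 0]
        if len(roots) != 1:
            raise OntologyError(f"hierarchy must have a single root, found {sorted(roots)}")

    def _invalidate(self) -> None:
        self._depth_cache = None
        self._sim_cache: dict = {}

    # -- queries ----------------------------------------------------------

    @property
    def classes(self) -> set:
        return set(self._g.nodes)

    @property
    def root(self) -> str:
        roots = [n for n in self._g if self._g.out_degree(n) == 0]
        if len(roots) != 1:
            raise OntologyError(f"hierarchy must have a single root, found {sorted(roots)}")
        return roots[0]

    def has_class(self, name: str) -> bool:
        return name in self._g

    def parents(self, cls: str) -> list:
        return sorted(self._g.successors(cls))

    def ancestors(self, cls: str, include_self: bool = False) -> set:
        """All superclasses of ``cls`` (transitive)."""
        if cls not in self._g:
            raise OntologyError(f"unknown class {cls!r}")
        anc = nx.descendants(self._g, cls)     # edges point child -> parent
        if include_self:
            anc = anc | {cls}
        return anc

    def is_subclass_of(self, cls: str, ancestor: str) -> bool:
        return cls == ancestor or ancestor in self.ancestors(cls)

    def depth(self, cls: str) -> int:
        """Edges on the longest path from ``cls`` up to the root (root = 0)."""
        if getattr(self, "_depth_cache", None) is None:
            self._depth_cache = {}
            for node in nx.topological_sort(self._g.reverse(copy=False)):
                parents = list(self._g.successors(node))
                self._depth_cache[node] = (
                    0 if not parents else 1 + max(self._depth_cache[p] for p in parents)
                )
        return self._depth_cache[cls]

    # -- instances --------------------------------------------------------

    def classes_of_instance(self, name: str, kb: Optional[KnowledgeBase] = None) -> set:
        """Asserted classes of an instance; KB ``type`` facts are consulted
        for entities (patients) typed in the data rather than the ontology."""
        classes = set(self.instances.get(name, ()))
        if kb is not None:
            classes |= {f.value for f in kb.facts_for("type") if f.subject == name
                        and isinstance(f.value, str) and f.value in self._g}
        return classes

    def most_specific_class(self, name: str, kb: Optional[KnowledgeBase] = None) -> Optional[str]:
        classes = self.classes_of_instance(name, kb)
        if not classes:
            return None
        return min(classes, key=lambda c: (-self.depth(c), c))

    def is_instance_of(self, name, cls: str, kb: Optional[KnowledgeBase] = None) -> bool:
        """True when ``name`` is an instance of ``cls`` or any subclass."""
        if cls not in self._g:
            raise OntologyError(f"unknown class in type constraint: {cls!r}")
        if not isinstance(name, str):
            return False
        return any(self.is_subclass_of(c, cls) for c in self.classes_of_instance(name, kb))

    def ancestor_chain(self, name: str, kb: Optional[KnowledgeBase] = None) -> list:
        """Classes of an instance (or class) ordered nearest-first, ending at the root."""
        if name in self._g:
            start = [name]
        else:
            classes = self.classes_of_instance(name, kb)
            if not classes:
                return []
            start = sorted(classes, key=lambda c: (-self.depth(c), c))
        seen, chain = set(), []
        frontier = list(start)
        while frontier:
            nxt = []
            for c in frontier:
                if c not in seen:
                    seen.add(c)
                    chain.append(c)
                    nxt.extend(self.parents(c))
            frontier = sorted(set(nxt), key=lambda c: (-self.depth(c), c))
        return chain

    # -- similarity -------------------------------------------------------

    def _resolve(self, arg: str) -> tuple:
        """Resolve class-or-instance to (anchor class, extra edge count)."""
        if arg in self._g:
            return arg, 0
        cls = self.most_specific_class(arg)
        if cls is None:
            raise OntologyError(f"cannot resolve {arg!r} as class or instance")
        return cls, 1

    def least_common_subsumer(self, c1: str, c2: str) -> str:
        """Deepest common ancestor-or-self; ties broken lexicographically."""
        a1, _ = self._resolve(c1)
        a2, _ = self._resolve(c2)
        common = self.ancestors(a1, include_self=True) & self.ancestors(a2, include_self=True)
        if not common:
            raise OntologyError(f"no common subsumer for {c1!r} and {c2!r}")
        return min(common, key=lambda c: (-self.depth(c), c))

    def similarity_counts(self, c1: str, c2: str) -> SimilarityCounts:
        key = (c1, c2) if c1 <= c2 else (c2, c1)
        cached = self._sim_cache.get(key)
        if cached is not None:
            if (c1, c2) != key:
                return SimilarityCounts(cached.n2, cached.n1, cached.n3, cached.c3)
            return cached
        counts = self._similarity_counts(c1, c2)
        self._sim_cache[key] = counts if (c1, c2) == key else SimilarityCounts(
            counts.n2, counts.n1, counts.n3, counts.c3)
        return counts

    def _similarity_counts(self, c1: str, c2: str) -> SimilarityCounts:
        a1, e1 = self._resolve(c1)
        a2, e2 = self._resolve(c2)
        c3 = self.least_common_subsumer(a1, a2)
        n1 = nx.shortest_path_length(self._g, a1, c3) + e1
        n2 = nx.shortest_path_length(self._g, a2, c3) + e2
        if c1 == c2:
            n1 = n2 = 0
        return SimilarityCounts(n1, n2, self.depth(c3), c3)

    def consim(self, c1: str, c2: str) -> float:
        """Wu–Palmer similarity in [0, 1]; 0 when the subsumer is the root."""
        counts = self.similarity_counts(c1, c2)
        if counts.n3 == 0:
            return 0.0
        return 2.0 * counts.n3 / (counts.n1 + counts.n2 + 2.0 * counts.n3)


# ---------------------------------------------------------------------------
# Materialization
# ---------------------------------------------------------------------------

def materialize_types(kb: KnowledgeBase, onto: ConceptHierarchy) -> set:
    """Run ontology inferencing to fixpoint and assert the results.

    Adds, with provenance ``ontology``: (i) the supertype closure of every
    ``type`` fact, and (ii) for each existential class definition,
    ``type(e, Defined)`` for every entity already typed with the required
    superclass that holds ``property(e, v)`` with ``v`` an instance of the
    filler class or a subclass.  Idempotent and monotone; unknown classes
    or instances are skipped with a warning.
    """
    inferred: set = set()
    changed = True
    while changed:
        changed = False
        for f in list(kb.facts_for("type")):
            cls = f.value
            if not isinstance(cls, str) or not onto.has_class(cls):
                logger.warning("type fact %s references unknown class; skipped", f)
                continue
            for anc in onto.ancestors(cls):
                nf = Fact("type", f.subject, anc, provenance="ontology")
                if kb.add_fact(nf):
                    inferred.add(nf)
                    changed = True
        for d in onto.definitions:
            typed = {f.subject for f in kb.facts_for("type")
                     if f.value == d.required_superclass}
            for f in kb.facts_for(d.property):
                if f.subject not in typed:
                    continue
                if onto.is_instance_of(f.value, d.filler_class, kb):
                    nf = Fact("type", f.subject, d.defined_class,
                              provenance="ontology", supporting=d)
                    if kb.add_fact(nf):
                        inferred.add(nf)
                        changed = True
    return inferred
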