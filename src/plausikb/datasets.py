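"""Hepatitis cohort data: schema, ingestion, enrichment, synthetic
generation and MCAR degradation.

The reference cohort describes 155 hepatitis patients by 19 attributes plus
a survival label.  Attributes map to predicates as follows: demographic
``sex``; medications ``onMed``/``noOnMed`` (enriched with concrete
medication instances); symptoms ``symptom``/``noSymptom``; physical signs
``physicalSign``/``noPhysicalSign``; pathology ``pathology``/
``noPathology``; five continuous lab values plus ``age`` as scalar facts.
The label becomes ``live(P, true|false)`` and is held out as gold, never
asserted into the KB.

The synthetic generator emulates the reference cohort's published
categorical proportions, continuous ranges and per-attribute missingness
(155 x 19 = 2945 attribute slots, 167 of them empty), so that the full
pipeline runs without the original file.  MCAR degradation removes each
present attribute fact independently with probability p — missingness
independent of all values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import Fact, KBError, KnowledgeBase
from .ontology import ClassDefinition, ConceptHierarchy


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttributeSpec:
    """One cohort attribute: predicate mapping plus reference distribution
    (counts out of 155 patients; categorical counts that do not sum to 155
    encode the reference cohort's pre-existing missing values)."""

    name: str
    kind: str                      # 'posneg' | 'enum' | 'continuous'
    predicate: str                 # positive-form predicate
    negative_predicate: Optional[str] = None
    value: Optional[str] = None    # instance used as the fact value (posneg)
    counts: Optional[dict] = None  # category -> reference count
    rng_range: Optional[tuple] = None
    missing: int = 0
    integer: bool = True
    medication_class: Optional[str] = None


def _posneg(name, predicate, value, pos, neg, missing=0, medication_class=None,
            negative_predicate=None):
    return AttributeSpec(name, "posneg", predicate,
                         negative_predicate or "no" + predicate[0].upper() + predicate[1:],
                         value, {"pos": pos, "neg": neg}, missing=missing,
                         medication_class=medication_class)


REFERENCE_N = 155

COHORT_SCHEMA: List[AttributeSpec] = [
    AttributeSpec("age", "continuous", "age", rng_range=(7, 78), missing=0),
    AttributeSpec("sex", "enum", "sex", counts={"male": 139, "female": 16}),
    _posneg("steroids", "onMed", "steroids", 78, 76, missing=1, medication_class="Steroid"),
    _posneg("antivirals", "onMed", "antivirals", 131, 24, medication_class="Antiviral"),
    _posneg("fatigue", "symptom", "fatigue", 54, 100, missing=1),
    _posneg("malaise", "symptom", "malaise", 93, 61, missing=1),
    _posneg("anorexia", "symptom", "anorexia", 122, 32, missing=1),
    _posneg("bigLiver", "physicalSign", "bigLiver", 120, 25, missing=10),
    _posneg("firmLiver", "physicalSign", "firmLiver", 84, 60, missing=11),
    _posneg("spleenPalpable", "physicalSign", "spleenPalpable", 120, 30, missing=5),
    _posneg("spiders", "physicalSign", "spiders", 99, 51, missing=5),
    _posneg("ascites", "physicalSign", "ascites", 130, 20, missing=5),
    _posneg("varices", "physicalSign", "varices", 132, 18, missing=5),
    AttributeSpec("bilirubin", "continuous", "bilirubin", rng_range=(0.3, 8.0),
                  missing=6, integer=False),
    AttributeSpec("alkPhosphate", "continuous", "alkPhosphate", rng_range=(26, 295), missing=29),
    AttributeSpec("sgot", "continuous", "sgot", rng_range=(14, 648), missing=4),
    AttributeSpec("albumin", "continuous", "albumin", rng_range=(2.1, 6.4),
                  missing=16, integer=False),
    AttributeSpec("protime", "continuous", "protime", rng_range=(0, 100), missing=67),
    _posneg("histology", "pathology", "histology", 70, 85),
]

LABEL_COUNTS = {"live": 123, "die": 32}

N_ATTRIBUTES = len(COHORT_SCHEMA)          # 19 attribute slots per patient

MEDICATION_INSTANCES = {
    "Steroid": ["Cortisone", "Prednisone", "Dexamethasone"],
    "Antiviral": ["InterferonAlfa2", "Lamivudine", "Adefovir"],
}

DISEASE_INSTANCES = ["hepatitis_A", "hepatitis_B", "hepatitis_C"]

SCHEMA_PREDICATES = {
    "type", "hasDisease", "live",
    *(a.predicate for a in COHORT_SCHEMA),
    *(a.negative_predicate for a in COHORT_SCHEMA if a.negative_predicate),
}


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

def hepatitis_ontology() -> ConceptHierarchy:
    """The enriched hepatitis concept hierarchy.

    Attribute categories become classes under the root, medications are
    specialized into concrete instances, and ``LiverDiseasePatient`` is
    defined existentially as a patient with some recorded liver disease.
    The exact hierarchy published with the original system is not public;
    this reconstruction follows the documented category structure.
    """
    o = ConceptHierarchy()
    o.add_class("Thing")
    o.add_class("Patient", "Thing")
    o.add_class("LiverDiseasePatient", "Patient")
    o.add_class("Disease", "Thing")
    o.add_class("LiverDisease", "Disease")
    o.add_class("Hepatitis", "LiverDisease")
    o.add_class("Medication", "Thing")
    o.add_class("Steroid", "Medication")
    o.add_class("Antiviral", "Medication")
    o.add_class("Symptom", "Thing")
    o.add_class("PhysicalSign", "Thing")
    o.add_class("LiverIssue", "PhysicalSign")
    o.add_class("VeinIssue", "PhysicalSign")
    o.add_class("Pathology", "Thing")
    o.add_class("Demographic", "Thing")
    for d in DISEASE_INSTANCES:
        o.add_instance(d, "Hepatitis")
    for cls, meds in MEDICATION_INSTANCES.items():
        for m in meds:
            o.add_instance(m, cls)
    for s in ("fatigue", "malaise", "anorexia"):
        o.add_instance(s, "Symptom")
    for s in ("firmLiver", "bigLiver"):
        o.add_instance(s, "LiverIssue")
    o.add_instance("varices", "VeinIssue")
    for s in ("ascites", "spleenPalpable", "spiders"):
        o.add_instance(s, "PhysicalSign")
    o.add_instance("histology", "Pathology")
    o.add_instance("male", "Demographic")
    o.add_instance("female", "Demographic")
    o.add_definition(ClassDefinition("LiverDiseasePatient", "Patient",
                                     "hasDisease", "LiverDisease"))
    o.validate()
    return o


# ---------------------------------------------------------------------------
# Synthetic cohort generation
# ---------------------------------------------------------------------------

def _add_attribute_fact(kb: KnowledgeBase, spec: AttributeSpec, patient: str,
                        outcome, rng) -> None:
    if spec.kind == "continuous":
        lo, hi = spec.rng_range
        v = rng.uniform(lo, hi)
        value = int(round(v)) if spec.integer else round(float(v), 1)
        kb.add_fact(Fact(spec.predicate, patient, value, attribute=spec.name))
    elif spec.kind == "enum":
        kb.add_fact(Fact(spec.predicate, patient, outcome, attribute=spec.name))
    elif outcome == "pos":
        if spec.medication_class:
            value = MEDICATION_INSTANCES[spec.medication_class][
                rng.integers(len(MEDICATION_INSTANCES[spec.medication_class]))]
        else:
            value = spec.value
        kb.add_fact(Fact(spec.predicate, patient, value, attribute=spec.name))
    else:
        kb.add_fact(Fact(spec.negative_predicate, patient, spec.value, attribute=spec.name))


def generate_synthetic_cohort(n: int = REFERENCE_N, seed: int = 0,
                              schema: List[AttributeSpec] = COHORT_SCHEMA,
                              ontology: Optional[ConceptHierarchy] = None,
                              ) -> Tuple[KnowledgeBase, Dict[str, bool]]:
    """Sample a synthetic cohort reproducing the reference distributions.

    Per-attribute pre-existing missingness is allocated exactly (scaled to
    ``n``); categorical outcomes are sampled at the reference pos/neg
    proportions; continuous values uniformly over the published ranges.
    Enrichment assigns each patient a hepatitis instance and each
    positively-medicated patient a concrete medication instance.
    Reproducible per seed; returns (KB, gold labels).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    kb = KnowledgeBase(ontology=ontology)
    patients = [f"p{i}" for i in range(1, n + 1)]
    for p in patients:
        kb.add_fact(Fact("type", p, "Patient"))
        kb.add_fact(Fact("hasDisease", p, DISEASE_INSTANCES[rng.integers(3)]))
    for spec in schema:
        n_missing = int(round(spec.missing * n / REFERENCE_N))
        missing_idx = set(rng.choice(n, size=n_missing, replace=False).tolist())
        for i, p in enumerate(patients):
            if i in missing_idx:
                continue
            outcome = None
            if spec.kind == "enum":
                cats = sorted(spec.counts)
                probs = np.array([spec.counts[c] for c in cats], dtype=float)
                outcome = cats[rng.choice(len(cats), p=probs / probs.sum())]
            elif spec.kind == "posneg":
                p_pos = spec.counts["pos"] / (spec.counts["pos"] + spec.counts["neg"])
                outcome = "pos" if rng.random() < p_pos else "neg"
            _add_attribute_fact(kb, spec, p, outcome, rng)
    p_live = LABEL_COUNTS["live"] / sum(LABEL_COUNTS.values())
    labels = {p: bool(rng.random() < p_live) for p in patients}
    return kb, labels


# ---------------------------------------------------------------------------
# MCAR degradation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegradationSpec:
    """MCAR removal: each present attribute fact is independently dropped
    with probability ``fraction``; labels and enrichment facts are exempt."""

    fraction: float
    replicates: int = 5
    seed: int = 0
    mechanism: str = "MCAR"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.mechanism != "MCAR":
            raise ValueError("only the MCAR mechanism is supported")


@dataclass
class DegradedReplicate:
    kb: KnowledgeBase
    removed: int
    total_missing: int           # pre-existing missing + removed


def attribute_facts(kb: KnowledgeBase) -> List[Fact]:
    return sorted((f for f in kb.facts() if f.attribute is not None),
                  key=lambda f: (str(f.subject), f.attribute, f.predicate, str(f.value)))


def missing_slots(kb: KnowledgeBase, n_attributes: int = N_ATTRIBUTES) -> int:
    """Pre-existing empty attribute slots: patients x attributes - present facts."""
    present = attribute_facts(kb)
    patients = {f.subject for f in kb.facts_for("type") if f.value == "Patient"}
    patients |= {f.subject for f in present}
    return len(patients) * n_attributes - len(present)


def mcar_degrade(kb: KnowledgeBase, spec: DegradationSpec) -> List[DegradedReplicate]:
    """Generate degraded replicate KBs under the MCAR mechanism.

    For every present attribute fact a uniform draw in [0, 1) is taken; the
    fact is left out when the draw exceeds ``1 - fraction``.  Gold labels
    are never stored in the KB and enrichment/type facts carry no attribute
    tag, so degradation touches attribute facts only.
    """
    rng = np.random.default_rng(spec.seed)
    present = attribute_facts(kb)
    pre_missing = missing_slots(kb)
    out: List[DegradedReplicate] = []
    for _ in range(spec.replicates):
        draws = rng.random(len(present))
        degraded = kb.copy()
        removed = 0
        for fact, u in zip(present, draws):
            if u > 1.0 - spec.fraction:
                degraded.retract_fact(fact)
                removed += 1
        out.append(DegradedReplicate(degraded, removed, pre_missing + removed))
    return out


# ---------------------------------------------------------------------------
# UCI ingestion
# ---------------------------------------------------------------------------

UCI_COLUMNS = ["class", "age", "sex", "steroids", "antivirals", "fatigue", "malaise",
               "anorexia", "bigLiver", "firmLiver", "spleenPalpable", "spiders",
               "ascites", "varices", "bilirubin", "alkPhosphate", "sgot", "albumin",
               "protime", "histology"]

_SPEC_BY_NAME = {a.name: a for a in COHORT_SCHEMA}


def read_uci_hepatitis(path, enrich: bool = True, seed: int = 0,
                       ontology: Optional[ConceptHierarchy] = None,
                       ) -> Tuple[KnowledgeBase, Dict[str, bool]]:
    """Read the UCI-format hepatitis CSV (``?`` = missing) into a KB.

    Coding: class 1=die 2=live; sex 1=male 2=female; binary attributes
    1=neg 2=pos.  One patient entity per row (p1..pN); ``?`` emits no fact;
    the class label is returned as gold, not asserted.  ``enrich`` assigns
    concrete medication and hepatitis instances with a seeded RNG, since
    the raw file records only medication classes.
    """
    df = pd.read_csv(path, header=None, na_values=["?"])
    if df.shape[1] != len(UCI_COLUMNS):
        raise KBError(f"expected {len(UCI_COLUMNS)} columns, found {df.shape[1]}")
    df.columns = UCI_COLUMNS
    rng = np.random.default_rng(seed)
    kb = KnowledgeBase(ontology=ontology)
    labels: Dict[str, bool] = {}
    for i, row in df.iterrows():
        patient = f"p{i + 1}"
        kb.add_fact(Fact("type", patient, "Patient"))
        if enrich:
            kb.add_fact(Fact("hasDisease", patient, DISEASE_INSTANCES[rng.integers(3)]))
        if not pd.isna(row["class"]):
            labels[patient] = int(row["class"]) == 2
        for name in UCI_COLUMNS[1:]:
            raw = row[name]
            if pd.isna(raw):
                continue
            spec = _SPEC_BY_NAME[name]
            if spec.kind == "continuous":
                value = int(raw) if spec.integer else float(raw)
                kb.add_fact(Fact(spec.predicate, patient, value, attribute=name))
            elif spec.kind == "enum":
                value = "male" if int(raw) == 1 else "female"
                kb.add_fact(Fact(spec.predicate, patient, value, attribute=name))
            else:
                outcome = "pos" if int(raw) == 2 else "neg"
                if outcome == "pos" and spec.medication_class and enrich:
                    meds = MEDICATION_INSTANCES[spec.medication_class]
                    kb.add_fact(Fact(spec.predicate, patient, meds[rng.integers(len(meds))],
                                     attribute=name))
                elif outcome == "pos":
                    kb.add_fact(Fact(spec.predicate, patient, spec.value, attribute=name))
                else:
                    kb.add_fact(Fact(spec.negative_predicate, patient, spec.value,
                                     attribute=name))
    return kb, labels
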