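# plausikb

Multi-strategy plausible reasoning over incomplete semantic medical
knowledge bases.

Clinical knowledge bases are chronically incomplete: patient records have
gaps, and much diagnostic knowledge is tacit.  A purely deductive engine
then simply fails to answer.  `plausikb` extends a deductive,
justification-producing rule engine with *plausible* (ampliative,
non-monotonic) inference so that queries unanswerable from the deductive
closure can still be justified tentatively — subject to expert
verification — and so that the coverage gain and correctness cost of doing
so can be measured under controlled missing-data conditions.

It is aimed at researchers in clinical decision support and
knowledge-based systems who want a small, fully inspectable engine for
experimenting with deduction + induction + analogy over RDF-style patient
data.

## What the engine does

1. **Deductive backward chaining** over Horn rules builds a
   *justification tree* for a query such as `live(p116, true)`.  Leaves
   are KB facts, ontology inferences, or explicitly `missing` premises.
2. **Ontology reasoning** materializes subclass closures and existential
   class definitions (e.g. `LiverDiseasePatient == Patient AND EXISTS
   hasDisease.LiverDisease`), resolving type premises.
3. **Analogical reasoning** fills a missing premise by knowledge transfer:
   a plausible rule "Q is plausibly determined by P" plus a reference
   entity holding both P and Q licenses transferring Q to a target that
   shares P (`consequent <~ condition` in the rule dialect).
4. **Inductive generalization** retrieves all entities sharing the missing
   feature, takes the conjunction of the conditions each shares with the
   target — exact matches, or type generalizations `(type C)` accepted when
   the Wu–Palmer conceptual similarity

   ConSim(C1, C2) = 2·N3 / (N1 + N2 + 2·N3)

   reaches a threshold τ (N3 = depth of the closest common subsumer C3,
   N1/N2 = edge distances of C1/C2 to C3) — and proposes candidate
   deductive rules ranked by positive coverage.
5. **Expert verification**: plausible inferences live in per-query working
   memory; a decision file of accepted/rejected fingerprints controls
   which are used, and only accepted items are materialized into the KB.
6. **Evaluation harness**: a synthetic 155-patient hepatitis cohort
   matching the published attribute distributions, MCAR degradation at a
   chosen missingness fraction, and cohort-level

   coverage = (total − unanswered) / total,
   correctness = (total − unanswered − incorrect) / (total − unanswered).

## Formats

* **KB facts**: a Turtle subset in one default namespace
  (`:p116 :physicalSign :varices .`, `:p116 a :Patient .`), or one ground
  literal per line (`physicalSign(p116, varices).`).  Negative
  observations use `no`-prefixed predicates (`noPhysicalSign`); absence of
  both polarities means *missing*, never false.
* **Ontology**: Turtle with `rdfs:subClassOf`, `rdf:type`, and
  `:onProperty`/`:someValuesFrom` for existential class definitions.
* **Rules**: one per line.  Deductive `head :- lit, lit, ... .`;
  plausible `consequent <~ condition .`.  Variables are a single
  upper-case letter plus optional digits (`P`, `X`, `Q1`); anything else
  is a constant, so `LiverDiseasePatient` and `InterferonAlfa2` are
  concept names.  Type restrictions are written `(type Antiviral)` (anonymous)
  or `(type Antiviral) M`.  Comparison predicates (`lessThan`, `between`,
  ...) are evaluated on scalars, not matched.

## Worked example

The packaged case study (`plausikb.casestudy`) reconstructs a queried
patient `p116` whose ascites and firm-liver findings are missing:

```bash
plausikb query demo/kb.ttl --ontology demo/ontology.ttl \
    --rules demo/rules.pl "live(p116, true)"
```

```
answered: True
live(p116, true)  [rule]
  age(p116, 38)  [fact]
  lessThan(38, 60)  [fact]  (builtin)
  type(p116, LiverDiseasePatient)  [ontology]
  physicalSign(p116, ascites)  [induction]
    onMed(p116, InterferonAlfa2)  [fact]
    physicalSign(p116, spleenPalpable)  [fact]
  physicalSign(p116, firmLiver)  [analogy]
```

Reading the tree: the age premise is an asserted fact; the type premise
was materialized from the existential definition (p116 has `hepatitis_B`,
an instance of a `LiverDisease` subclass); ascites was justified by an
induced rule; the firm liver was transferred by analogy.  With
`--strategy deductive` the same query prints `answered: False` with the
two physical-sign premises listed as missing.  `plausikb explain` shows
the underlying reasoning materials:

```
missing premise: physicalSign(p116, ascites)
  induced: physicalSign(P, ascites) :- onMed(P, (type Antiviral)), physicalSign(P, spleenPalpable).  coverage=3
    generalized onMed: ('InterferonAlfa2', 'Lamivudine') -> (type Antiviral), consim=0.667

missing premise: physicalSign(p116, firmLiver)
  analogy: rule [physicalSign(X, (type LiverIssue) L) <~ physicalSign(X, (type VeinIssue) V).] reference p75 shared varices -> inferred physicalSign(p116, firmLiver) (support 1)
```

The induced rule covers the three patients who share ascites (its
*positive coverage*); the medication condition was generalized to the
`Antiviral` class because the patients' concrete antivirals score
ConSim = 2·2/(1+1+2·2) = 0.667 ≥ τ = 0.5.

The same objects are available from Python:

```python
from plausikb import justify_query, parse_literal_text
from plausikb.casestudy import case_kb, case_ontology, case_rules

onto = case_ontology()
kb, labels = case_kb(onto)
_, plausible = case_rules()
res = justify_query(kb, onto, plausible, parse_literal_text("live(p116, true)"))
print(res.answered)            # True
print(res.tree.to_text())
```

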