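# Methods

## Model

`plausikb` implements a multi-strategy reasoning loop over a knowledge
base of ground binary facts `predicate(subject, value)`, Horn-style
deductive rules, plausible ("Q is plausibly determined by P") rules, and a
rooted concept DAG with instance typing and existential class
definitions.  A query is justified in stages:

1. *Ontology materialization.*  Supertype closures of all `type` facts
   and existential definitions (`Defined == Super AND EXISTS prop.Filler`)
   are computed to fixpoint and asserted with provenance `ontology`.
   Materialization is idempotent and monotone.
2. *Backward chaining.*  SLD resolution with rule order determining
   search order, goal-signature cycle detection and a depth limit
   (default 25).  If a complete proof exists the first one found is kept.
   Otherwise a single best-effort tree is built: per goal, facts are tried
   before rules (asserted facts before inferred ones), the rule yielding
   the fewest missing leaves wins (ties by file order), and unresolvable
   premises become `missing` leaves.  Comparison builtins (`lessThan`,
   `between`, ...) are evaluated, never matched; when their scalar
   argument is unavailable the scalar literal, not the builtin, is the
   missing leaf, so plausible reasoning targets the datum that is actually
   absent.
3. *Per missing premise, analogy then induction.*  The premise value is
   generalized along its ancestor chain nearest-first to select plausible
   rules; reference entities unifying both rule sides whose instantiated
   condition also holds for the target license a transfer.  Competing
   transferred values are all reported, ranked by how many references
   support them.  If no analogical inference matches the premise,
   induction is tried (below).  Resolved premises enter the per-query
   working memory and the tree is re-proved; the loop stops when the tree
   is complete or no premise makes progress.
4. *Verification.*  Without a decision file every plausible candidate is
   used (the "without expert verification" condition).  With one, only
   accepted fingerprints are used, and `apply_verification` recomputes
   dependent answers and materializes accepted items into the shared KB.
   Because rejection only removes inference options, verified answers are
   a subset of unverified answers.

## Inductive generalization

For a missing `feature(target, v)` all other entities holding `v` are
retrieved.  For each such sharer the conditions it shares with the target
are computed per predicate: exact common values, or — only when no exact
common value exists — a type generalization `(type L)` where `L` is the
least common subsumer of the most similar value pair and the pair's
Wu–Palmer similarity reaches τ.  Sharers with identical condition sets
aggregate into one candidate rule (head = premise with the subject
generalized, body = the shared condition set); aggregation is what gives
each candidate its evidence base, and its *positive coverage* is
recomputed from the KB as the number of entities satisfying body and
head.  Candidates are ranked by coverage (descending), body length
(ascending), then lexicographically.  An all-sharers conjunction would be
redundant here: every subset of the common conditions has identical
coverage, so grouping by per-sharer similarity sets is what produces
informative, distinct bodies.

## Conceptual similarity convention

ConSim(C1, C2) = 2·N3 / (N1 + N2 + 2·N3).  N1, N2, N3 are *edge* counts;
the root has depth 0, and named instances are treated as leaf nodes one
edge below their most specific asserted class.  Hence two distinct
antivirals score 2·2/(1+1+4) = 2/3 (similar but not identical), identical
arguments score exactly 1, and concepts whose only common subsumer is the
root score 0.  On DAGs the deepest common ancestor is chosen with
lexicographic tie-breaking; depth is the longest path to the root and N1/N2
use shortest ancestor paths.  These conventions are package choices where
the underlying measure is ambiguous at endpoints.

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ (`InductionConfig.tau`) | 0.5 | minimum ConSim for type-generalizing differing values; 0.5 admits same-class generalizations at depth ≥ 1 while rejecting cross-category ones in the hepatitis hierarchy |
| `min_coverage` | 2 | a candidate rule must be supported by at least two entities — a single sharer is anecdote, not generalization |
| `blacklist` | `{sex}` | attributes excluded from rule bodies as clinically irrelevant to the target query; configurable per domain |
| `bin_continuous` | off | continuous attributes (age, lab values) are excluded from induction bodies; optional equal-width binning over the observed range can re-admit them |
| `depth_limit` | 25 | backward-chaining recursion bound with cycle detection |

## Synthetic cohort and MCAR harness

The generator emulates the published reference cohort: 155 patients × 19
attributes (2945 slots).  Categorical attributes are sampled at the
published pos/neg proportions; continuous attributes uniformly over the
published ranges; per-attribute pre-existing missingness is allocated
exactly (scaled for other cohort sizes), totalling 167 empty slots and
2778 present facts at n = 155.  The per-attribute split of the 122
missing continuous values follows the public dataset documentation;
categorical missing counts are derivable from the published
per-attribute totals.  Enrichment assigns every patient a hepatitis
instance and every positively medicated patient a concrete medication
instance, uniformly with the seeded generator, mirroring how the original
raw table was lifted to an ontology-backed KB.  The survival label is
sampled at the published 123/155 live proportion, *independently of the
attributes*.

MCAR degradation removes each present attribute fact independently with
probability p (draw > 1 − p), leaving labels, types and enrichment facts
untouched; the removed-count distribution is Binomial(#present, p), so at
the reference scale the expected total missing is 167 + 2778·p
(≈306/445/584/723 at 5/10/15/20%).

What the synthetic cohort does **not** emulate: correlations between
attributes, between attributes and outcome, and the original expert rule
base (9 deductive + 7 plausible rules, unpublished).  Passing tests on it
therefore demonstrate engine correctness — accounting arithmetic,
missing-data statistics, strategy behaviour — not clinical validity of
any induced rule, and end-to-end coverage/correctness on synthetic
cohorts characterize the pipeline rather than reproduce the original
study tables.  The packaged case-study fixture (p116/p75 and the ascites
cohort) is likewise a reconstruction from published prose and is flagged
as such in its docstrings.

## Numerical and design choices

* Facts compare by their triple only; provenance is metadata.  Asserted
  facts are immutable under reasoning, and retracting all inferred
  knowledge restores the asserted state exactly (non-monotonic contract).
* Rule-dialect variables are a single upper-case letter plus optional
  digits, so capitalized concept names parse as constants without
  quoting.
* Coverage/correctness percentages round to the nearest whole percent,
  ties away from zero; replicate averages are means of full-precision
  ratios, rounded last.  Correctness is undefined (reported as null) when
  nothing is answered.
* A query proved for `live(P, true)` against a "die" label counts as
  incorrect; an unprovable query counts as unanswered, never as a
  negative prediction.
* Analogy is attempted before induction per premise; when analogy
  succeeds, induced alternatives are still listed (in `explain` /
  `collect_alternatives`) but not auto-applied.  A single resolution pass
  per premise is made each round, with re-proving between rounds.

## Known limitations

* No negation-as-failure in rule bodies and no probabilistic weighting of
  proofs or plausible inferences.
* Ontology support is deliberately small: subclass DAG, instance typing,
  existential definitions.  No property hierarchies, cardinality
  restrictions, or consistency checking.
* Induction requires all sharers in a group to match each condition
  (conjunction semantics); majority-based bodies and negative-example
  pruning are out of scope, as is automatic rule merging.
* The best-effort proof keeps the first complete proof per premise, so
  justification trees are deterministic but not guaranteed minimal.
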