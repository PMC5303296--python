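"""Cohort evaluation: coverage and correctness of survival queries.

For every patient P with a gold outcome label, the engine justifies
``live(P, true)``.  An answered query is correct iff the gold label is
"live"; inability to justify counts as unanswered, never as a "die"
prediction.  Coverage is the fraction of queries answered at all;
correctness the fraction of answered queries that are correct::

    coverage    = (total - unanswered) / total
    correctness = (total - unanswered - incorrect) / (total - unanswered)

Percentages are reported rounded to the nearest whole percent (ties away
from zero) alongside the full-precision ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

from .controller import DecisionFile, justify_query
from .induction import InductionConfig
from .model import Const, KnowledgeBase, Literal, fingerprint_fact, fingerprint_rule
from .ontology import ConceptHierarchy


@dataclass
class EvalCounts:
    total: int
    correct: int
    incorrect: int
    unanswered: int
    plausible_rules_used: int = 0
    plausible_facts_used: int = 0

    def __post_init__(self) -> None:
        if self.correct + self.incorrect + self.unanswered != self.total:
            raise ValueError("correct + incorrect + unanswered must equal total")


@dataclass
class CoverageCorrectness:
    coverage: float
    correctness: Optional[float]
    coverage_pct: int
    correctness_pct: Optional[int]


def _round_pct(x: float) -> int:
    return int(math.floor(x * 100 + 0.5))


def coverage_correctness(counts: EvalCounts) -> CoverageCorrectness:
    """Coverage/correctness ratios of an evaluation, rounded and exact."""
    if counts.total == 0:
        raise ValueError("total must be positive")
    answered = counts.total - counts.unanswered
    coverage = answered / counts.total
    if answered == 0:
        return CoverageCorrectness(coverage, None, _round_pct(coverage), None)
    correctness = (answered - counts.incorrect) / answered
    return CoverageCorrectness(coverage, correctness,
                               _round_pct(coverage), _round_pct(correctness))


def evaluate_cohort(kb: KnowledgeBase, onto: ConceptHierarchy, plausible_rules,
                    labels: Dict[str, bool], strategy: str = "deductive",
                    decisions: Optional[DecisionFile] = None,
                    config: InductionConfig = InductionConfig(),
                    query_predicate: str = "live") -> EvalCounts:
    """Run the survival query for every labelled patient and tally outcomes.

    ``labels`` maps patient id -> True (live) / False (die); the labels are
    gold data and must not be present in the KB.  Plausible rules and facts
    are counted deduplicated across the whole cohort.
    """
    correct = incorrect = unanswered = 0
    rules_used: set = set()
    facts_used: set = set()
    for patient in sorted(labels):
        query = Literal(query_predicate, (Const(patient), Const("true")))
        res = justify_query(kb, onto, plausible_rules, query,
                            strategy=strategy, decisions=decisions, config=config)
        outcome = res.score(labels[patient])
        if outcome == "unanswered":
            unanswered += 1
        elif outcome == "correct":
            correct += 1
        else:
            incorrect += 1
        rules_used |= {fingerprint_rule(r) for r in res.plausible_rules_used}
        facts_used |= {fingerprint_fact(f) for f in res.plausible_facts_used}
    return EvalCounts(len(labels), correct, incorrect, unanswered,
                      plausible_rules_used=len(rules_used),
                      plausible_facts_used=len(facts_used))


def average_counts(counts: Sequence[EvalCounts]) -> CoverageCorrectness:
    """Average coverage/correctness across replicate datasets (mean of the
    full-precision ratios, then rounded — matching replicate-table summaries)."""
    covs, corrs = [], []
    for c in counts:
        cc = coverage_correctness(c)
        covs.append(cc.coverage)
        if cc.correctness is not None:
            corrs.append(cc.correctness)
    coverage = sum(covs) / len(covs)
    correctness = sum(corrs) / len(corrs) if corrs else None
    return CoverageCorrectness(coverage, correctness, _round_pct(coverage),
                               None if correctness is None else _round_pct(correctness))
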