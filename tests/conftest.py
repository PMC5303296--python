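import random

import pytest

from plausikb.casestudy import case_kb, case_ontology, case_rules
from plausikb.model import Const, DeductiveRule, Fact, KnowledgeBase, Literal, Var


@pytest.fixture(scope="session")
def onto():
    return case_ontology()


@pytest.fixture()
def case(onto):
    """(kb, labels, deductive rules, plausible rules) for the p116 case study."""
    kb, labels = case_kb(onto)
    deductive, plausible = case_rules()
    return kb, labels, deductive, plausible


def random_kb(rng: random.Random, n_entities=5, n_preds=3, n_values=3,
              n_facts=15, n_rules=5):
    """A random ground KB plus simple propositional-style rules.

    Rules have the shape ``p(P, v) :- q(P, w)[, r(P, u)]`` so the
    deductive closure is computable by naive forward chaining.
    """
    entities = [f"e{i}" for i in range(n_entities)]
    preds = [f"q{i}" for i in range(n_preds)]
    values = [f"v{i}" for i in range(n_values)]
    kb = KnowledgeBase()
    for _ in range(n_facts):
        kb.add_fact(Fact(rng.choice(preds), rng.choice(entities), rng.choice(values)))
    for _ in range(n_rules):
        head = Literal(rng.choice(preds), (Var("P"), Const(rng.choice(values))))
        body = tuple(Literal(rng.choice(preds), (Var("P"), Const(rng.choice(values))))
                     for _ in range(rng.randint(1, 2)))
        kb.add_rule(DeductiveRule(head, body))
    return kb, entities, preds, values
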