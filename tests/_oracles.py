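"""Independent brute-force oracles for the rule-mining suite.

These enumerate every subset / every rule split directly by scanning the
transactions; they share no code path with the level-wise miner.
"""

import math
from itertools import combinations

import pytest

from comorbid_arm.arm import apriori, generate_rules


def brute_frequent(transactions, n, min_support):
    universe = sorted(set().union(*transactions)) if transactions else []
    out = {}
    for size in range(1, len(universe) + 1):
        for items in combinations(universe, size):
            s = frozenset(items)
            count = sum(1 for t in transactions if s <= t)
            if count / n > min_support:
                out[s] = count
    return out


def brute_rules(transactions, n, min_support, min_confidence, min_lift,
                max_consequent_size=1):
    counts = brute_frequent(transactions, n, min_support)
    rules = {}
    for items, count in counts.items():
        if len(items) < 2:
            continue
        for k in range(1, max_consequent_size + 1):
            for cons in combinations(sorted(items), k):
                cons = frozenset(cons)
                ante = items - cons
                if not ante:
                    continue
                count_a = sum(1 for t in transactions if ante <= t)
                count_b = sum(1 for t in transactions if cons <= t)
                support = count / n
                confidence = count / count_a
                lift = support / ((count_a / n) * (count_b / n))
                if confidence > min_confidence and lift > min_lift:
                    rules[(ante, cons)] = (
                        count, support, confidence, lift,
                        math.sqrt(support * lift),
                    )
    return rules


def random_transactions(rng, max_items=10, max_tx=200):
    items = [f"I{j}" for j in range(rng.randint(2, max_items))]
    n = rng.randint(1, max_tx)
    return [
        frozenset(it for it in items if rng.random() < rng.random())
        for _ in range(n)
    ], n


def assert_equals_oracle(transactions, n, min_support, min_confidence, min_lift,
                         max_consequent_size=1):
    frequent = apriori(transactions, n, min_support)
    expected = brute_frequent(transactions, n, min_support)
    assert {fi.items: fi.count for fi in frequent} == expected
    for fi in frequent:
        assert fi.support == pytest.approx(fi.count / n, abs=0)
    rules = generate_rules(frequent, n, min_confidence, min_lift,
                           max_consequent_size)
    expected_rules = brute_rules(transactions, n, min_support, min_confidence,
                                 min_lift, max_consequent_size)
    got = {(r.antecedent, r.consequent): r for r in rules}
    assert set(got) == set(expected_rules)
    for key, (count, support, confidence, lift, is_score) in expected_rules.items():
        r = got[key]
        assert r.count == count
        assert r.support == pytest.approx(support, abs=1e-12)
        assert r.confidence == pytest.approx(confidence, abs=1e-12)
        assert r.lift == pytest.approx(lift, abs=1e-12)
        assert r.is_score == pytest.approx(is_score, abs=1e-12)
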