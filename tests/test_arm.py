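import math
import random
from itertools import combinations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import assert_equals_oracle, random_transactions
from comorbid_arm import datasets
from comorbid_arm.arm import (
    AssociationRule,
    apriori,
    build_transactions,
    compute_metrics,
    generate_rules,
    rank_rules,
    rule_label,
)

# --- compute_metrics ----------------------------------------------------


@pytest.mark.parametrize(
    "counts,expected",
    [
        # published DM->HTN reconstruction
        ((11740, 21893, 34665, 169959), (0.069, 0.536, 2.629, 0.426)),
        # (HTN, Liver)->DM
        ((1964, 4534, 21893, 169959), (0.012, 0.433, 3.363, 0.197)),
        ((0, 10, 10, 100), (0.0, 0.0, 0.0, 0.0)),
        ((50, 50, 50, 50), (1.0, 1.0, 1.0, 1.0)),
    ],
)
def test_compute_metrics_examples(counts, expected):
    from comorbid_arm.stats import round_half_up

    m = compute_metrics(*counts)
    assert tuple(round_half_up(v, 3) for v in m) == expected


def test_compute_metrics_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        compute_metrics(20, 10, 30, 100)  # joint exceeds a marginal
    with pytest.raises(ValueError, match="undefined"):
        compute_metrics(0, 0, 10, 100)


# --- apriori ------------------------------------------------------------


def test_apriori_handcrafted_matches_enumeration():
    tx = [
        frozenset("AB"), frozenset("ABC"), frozenset("AC"),
        frozenset("BD"), frozenset(),
    ]
    assert_equals_oracle(tx, 5, min_support=0.2, min_confidence=0.0, min_lift=0.0)


def test_apriori_support_threshold_is_strict():
    tx = [frozenset("A"), frozenset("B")]
    # support of each item is exactly 0.5: strictly-above excludes at 0.5
    assert apriori(tx, 2, min_support=0.5) == []
    assert len(apriori(tx, 2, min_support=0.49)) == 2


def test_apriori_single_transaction_boundary():
    frequent = apriori([frozenset("A")], 1, min_support=0.999)
    assert [(set(f.items), f.count) for f in frequent] == [({"A"}, 1)]


def test_apriori_refuses_empty_cohort():
    with pytest.raises(ValueError, match="N must be"):
        apriori([], 0, 0.1)


def test_apriori_anti_monotone_output():
    rng = random.Random(5)
    tx, n = random_transactions(rng)
    frequent = {fi.items for fi in apriori(tx, n, 0.05)}
    for items in frequent:
        for smaller in combinations(sorted(items), len(items) - 1):
            assert not smaller or frozenset(smaller) in frequent


# --- rule generation ----------------------------------------------------


def test_rule_with_lift_exactly_one_is_excluded():
    # A and B independent by construction: lift == 1 exactly
    tx = [frozenset("AB"), frozenset("A"), frozenset("B"), frozenset()]
    frequent = apriori(tx, 4, min_support=0.1)
    rules = generate_rules(frequent, 4, min_confidence=0.0, min_lift=1.0)
    assert rules == []


def test_perfect_cooccurrence_gives_confidence_one():
    tx = [frozenset("AB")] * 3 + [frozenset()] * 2
    frequent = apriori(tx, 5, min_support=0.1)
    rules = generate_rules(frequent, 5, min_confidence=0.1, min_lift=1.0)
    by_label = {r.label: r for r in rules}
    assert by_label["(A)→(B)"].confidence == 1.0
    assert by_label["(A)→(B)"].lift == pytest.approx(5 / 3)


def test_consequent_size_cap_is_configurable():
    tx = [frozenset("ABC")] * 4 + [frozenset()] * 4
    frequent = apriori(tx, 8, 0.1)
    single = generate_rules(frequent, 8, 0.0, 0.0, max_consequent_size=1)
    double = generate_rules(frequent, 8, 0.0, 0.0, max_consequent_size=2)
    assert all(len(r.consequent) == 1 for r in single)
    assert {len(r.consequent) for r in double} == {1, 2}


def test_randomized_oracle_equivalence_sample():
    rng = random.Random(20250923)
    for _ in range(25):
        tx, n = random_transactions(rng, max_items=7, max_tx=60)
        assert_equals_oracle(
            tx, n,
            min_support=rng.uniform(0.01, 0.3),
            min_confidence=rng.uniform(0.0, 0.5),
            min_lift=rng.choice([0.0, 1.0]),
            max_consequent_size=rng.choice([1, 2]),
        )


# --- ranking ------------------------------------------------------------


def test_reference_rules_rank_in_published_order():
    ranked = rank_rules(datasets.reference_rules())
    got = [(tuple(sorted(r.antecedent)), next(iter(r.consequent))) for r in ranked]
    assert got == datasets.PUBLISHED_RULE_ORDER


def test_rank_ties_resolved_deterministically():
    def rule(ante, cons, count, conf):
        return AssociationRule(frozenset(ante), frozenset(cons), count,
                               0.1, conf, 2.0, 0.447)

    a = rule({"A"}, {"B"}, 10, 0.5)
    b = rule({"B"}, {"A"}, 10, 0.3)
    c = rule({"C"}, {"D"}, 10, 0.3)
    ranked = rank_rules([c, b, a])
    assert [r.label for r in ranked] == ["(A)→(B)", "(B)→(A)", "(C)→(D)"]
    assert rank_rules([a, b, c]) == ranked  # stable across input order


def test_rank_empty_is_empty():
    assert rank_rules([]) == []


# --- symmetry and IS identity properties --------------------------------


@given(
    n=st.integers(10, 10_000),
    data=st.data(),
)
def test_lift_and_is_are_symmetric_and_is_identity_holds(n, data):
    count_a = data.draw(st.integers(1, n))
    count_b = data.draw(st.integers(1, n))
    lo = max(1, count_a + count_b - n)
    hi = min(count_a, count_b)
    count_ab = data.draw(st.integers(lo, hi))
    fwd = compute_metrics(count_ab, count_a, count_b, n)
    rev = compute_metrics(count_ab, count_b, count_a, n)
    assert fwd.lift == pytest.approx(rev.lift, abs=1e-12)
    assert fwd.is_score == pytest.approx(rev.is_score, abs=1e-12)
    # IS == support / sqrt(P(A) P(B)), algebraically sqrt(support * lift)
    alt = fwd.support / math.sqrt((count_a / n) * (count_b / n))
    assert fwd.is_score == pytest.approx(alt, abs=1e-12)
    assert fwd.confidence >= fwd.support - 1e-15


# --- transactions -------------------------------------------------------


def test_build_transactions_items_and_denominator(profiles_factory):
    profiles = profiles_factory(
        [
            (True, False, False, False, "Liver cancer"),
            (False, False, False, False, "Other"),
            (False, True, True, False, "Lung cancer"),
        ]
    )
    tx, n = build_transactions(profiles)
    assert n == 3
    assert tx[0] == frozenset({"DM", "Liver cancer"})
    assert tx[1] == frozenset({"Other"})
    assert tx[2] == frozenset({"HTN", "Hyperthyroidism", "Lung cancer"})
    tx2, n2 = build_transactions(profiles, include_other=False)
    assert n2 == 3 and tx2[1] == frozenset()


def test_empty_transactions_still_count_toward_n(profiles_factory):
    profiles = profiles_factory(
        [(True, True, False, False, "Liver cancer")] * 2
        + [(False, False, False, False, "Other")] * 8
    )
    tx, n = build_transactions(profiles, include_other=False)
    frequent = apriori(tx, n, min_support=0.1)
    supports = {frozenset(f.items): f.support for f in frequent}
    assert supports[frozenset({"DM"})] == pytest.approx(0.2)


def test_rule_label_formatting():
    assert rule_label({"HTN", "DM"}, {"Liver cancer"}) == "(DM, HTN)→(Liver cancer)"
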