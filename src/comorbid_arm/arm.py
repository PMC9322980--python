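"""Apriori association-rule mining over disease itemsets.

Transactions are per-episode disease sets drawn from the comorbidity flags
(DM, HTN, hyper-/hypothyroidism) and the cancer-site label. The miner is a
standard level-wise Apriori: size-k candidate itemsets are joined from
frequent (k-1)-itemsets sharing a (k-2)-prefix and pruned by
anti-monotonicity before counting.

Rule quality uses the four classical measures

    support(A->B)    = n(A and B) / N
    confidence(A->B) = n(A and B) / n(A)
    lift(A->B)       = support / (P(A) * P(B))
    IS(A->B)         = sqrt(support * lift)

IS (interest support, the cosine measure) equals support/sqrt(P(A)P(B))
and, like lift, is symmetric in A and B; rules are ranked by it.
All thresholds are strict: support > min_support, confidence >
min_confidence, lift > min_lift (so independence, lift = 1, is excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "FrequentItemset",
    "AssociationRule",
    "RuleMetrics",
    "build_transactions",
    "apriori",
    "compute_metrics",
    "generate_rules",
    "rank_rules",
    "rule_label",
    "mine_rules",
]

#: flag columns contributing items, and the item labels they map to
FLAG_ITEMS = [
    ("dm", "DM"),
    ("htn", "HTN"),
    ("hyperthyroidism", "Hyperthyroidism"),
    ("hypothyroidism", "Hypothyroidism"),
]


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset
    count: int
    support: float


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset
    consequent: frozenset
    count: int
    support: float
    confidence: float
    lift: float
    is_score: float

    @property
    def label(self) -> str:
        return rule_label(self.antecedent, self.consequent)


class RuleMetrics(NamedTuple):
    support: float
    confidence: float
    lift: float
    is_score: float


def rule_label(antecedent: Iterable[str], consequent: Iterable[str]) -> str:
    a = ", ".join(sorted(antecedent))
    c = ", ".join(sorted(consequent))
    return f"({a})→({c})"


def build_transactions(profiles, include_other: bool = True):
    """Per-episode disease itemsets from a profiles DataFrame.

    Every profile yields one transaction, possibly empty — episodes with
    no mined item still count toward the denominator N. ``include_other``
    controls whether the residual "Other" cancer-site label participates
    as an item.

    Returns ``(transactions, n)`` with transactions a list of frozensets.
    """
    n = len(profiles)
    transactions = []
    flags = {col: profiles[col].to_numpy() for col, _ in FLAG_ITEMS}
    sites = profiles["cancer_site"].to_numpy()
    for i in range(n):
        items = [label for col, label in FLAG_ITEMS if flags[col][i]]
        site = sites[i]
        if site != "Other" or include_other:
            items.append(site)
        transactions.append(frozenset(items))
    return transactions, n


def apriori(transactions, n: int, min_support: float = 0.01):
    """Mine all itemsets with support strictly above ``min_support``.

    Counting is vectorized over a boolean incidence matrix; candidate
    generation is the classical prefix join with subset pruning, which
    guarantees anti-monotonicity of the output.
    """
    if n < 1:
        raise ValueError("empty transaction set: N must be >= 1")
    if not (0 < min_support <= 1):
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")

    universe = sorted(set().union(*transactions)) if transactions else []
    index = {item: j for j, item in enumerate(universe)}
    incidence = np.zeros((len(transactions), len(universe)), dtype=bool)
    for i, t in enumerate(transactions):
        for item in t:
            incidence[i, index[item]] = True

    def count(items: tuple) -> int:
        cols = incidence[:, [index[it] for it in items]]
        return int(cols.all(axis=1).sum())

    out: list[FrequentItemset] = []
    # level 1
    counts1 = incidence.sum(axis=0)
    level = []
    for item, c in zip(universe, counts1):
        if c / n > min_support:
            level.append((item,))
            out.append(FrequentItemset(frozenset((item,)), int(c), int(c) / n))
    # level k from k-1 by prefix join + prune
    while level:
        level_set = set(level)
        candidates = []
        for a, b in combinations(level, 2):
            if a[:-1] == b[:-1]:
                cand = a + (b[-1],) if a[-1] < b[-1] else b + (a[-1],)
                if all(
                    tuple(s for s in cand if s != drop) in level_set for drop in cand
                ):
                    candidates.append(cand)
        next_level = []
        for cand in sorted(candidates):
            c = count(cand)
            if c / n > min_support:
                next_level.append(cand)
                out.append(FrequentItemset(frozenset(cand), c, c / n))
        level = next_level
    return out


def compute_metrics(count_ab: int, count_a: int, count_b: int, n: int) -> RuleMetrics:
    """Support, confidence, lift and IS from raw counts.

    ``count_ab`` is the joint count, ``count_a``/``count_b`` the marginal
    counts of antecedent and consequent, ``n`` the total number of
    transactions. A zero joint count yields all-zero metrics.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if count_a < 1 or count_b < 1:
        raise ValueError("rule undefined: antecedent/consequent count is zero")
    if not (0 <= count_ab <= min(count_a, count_b) <= n):
        raise ValueError(
            f"inconsistent counts: ab={count_ab}, a={count_a}, b={count_b}, n={n}"
        )
    if count_ab == 0:
        return RuleMetrics(0.0, 0.0, 0.0, 0.0)
    support = count_ab / n
    confidence = count_ab / count_a
    lift = support / ((count_a / n) * (count_b / n))
    return RuleMetrics(support, confidence, lift, math.sqrt(support * lift))


def generate_rules(
    frequent,
    n: int,
    min_confidence: float = 0.1,
    min_lift: float = 1.0,
    max_consequent_size: int = 1,
):
    """Emit rules from frequent itemsets under strict quality thresholds.

    Every frequent itemset of size >= 2 is split into antecedent ->
    consequent for each consequent of size up to ``max_consequent_size``;
    the rule is kept iff confidence > min_confidence and lift > min_lift.
    Antecedent/consequent counts are looked up among the frequent
    itemsets, which anti-monotonicity guarantees to be present.
    """
    counts = {fi.items: fi.count for fi in frequent}
    rules = []
    for fi in frequent:
        if len(fi.items) < 2:
            continue
        items = sorted(fi.items)
        for k in range(1, max_consequent_size + 1):
            if k >= len(items):
                break
            for consequent in combinations(items, k):
                cons = frozenset(consequent)
                ante = fi.items - cons
                try:
                    count_a, count_b = counts[ante], counts[cons]
                except KeyError as exc:  # violated anti-monotonicity
                    raise RuntimeError(
                        f"missing sub-itemset count for rule {rule_label(ante, cons)}"
                    ) from exc
                m = compute_metrics(fi.count, count_a, count_b, n)
                if m.confidence > min_confidence and m.lift > min_lift:
                    rules.append(
                        AssociationRule(
                            ante, cons, fi.count,
                            m.support, m.confidence, m.lift, m.is_score,
                        )
                    )
    return rules


def rank_rules(rules):
    """Deterministic total order: IS desc, count desc, confidence desc, label.

    When a bidirectional pair ties on IS and count (it always does — both
    are symmetric), the higher-confidence direction is listed first.
    """
    return sorted(
        rules,
        key=lambda r: (-r.is_score, -r.count, -r.confidence, r.label),
    )


def mine_rules(
    profiles,
    min_support: float = 0.01,
    min_confidence: float = 0.1,
    min_lift: float = 1.0,
    max_consequent_size: int = 1,
    include_other: bool = True,
):
    """End-to-end: profiles -> ranked rules."""
    transactions, n = build_transactions(profiles, include_other=include_other)
    frequent = apriori(transactions, n, min_support)
    rules = generate_rules(frequent, n, min_confidence, min_lift, max_consequent_size)
    return rank_rules(rules)


def rules_frame(rules):
    """Ranked rules as a report DataFrame (metrics rounded half-up, 3 dp)."""
    import pandas as pd

    from .stats import round_half_up

    rows = [
        {
            "rank": i + 1,
            "rule": r.label,
            "count": r.count,
            "support": round_half_up(r.support, 3),
            "confidence": round_half_up(r.confidence, 3),
            "lift": round_half_up(r.lift, 3),
            "IS": round_half_up(r.is_score, 3),
        }
        for i, r in enumerate(rules)
    ]
    return pd.DataFrame(
        rows, columns=["rank", "rule", "count", "support", "confidence", "lift", "IS"]
    )
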