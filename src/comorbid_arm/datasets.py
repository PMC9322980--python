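"""Published summary data of the 2009-2018 KNHDIS adult cancer cohort.

The Korea National Hospital Discharge In-depth Injury Survey (KNHDIS)
microdata are access-restricted; what is publicly available are summary
cross-tabulations of the N = 169,959 discharge episodes with a malignant
principal diagnosis (C00-C97): demographic marginals, per-site prevalence
of diabetes mellitus (DM) and hypertension (HTN), the joint counts behind
the 22 published comorbidity association rules, and the logistic
mortality coefficients.

These counts serve two purposes here: they parameterize the defaults of
:mod:`comorbid_arm.simulate`, and they are the printed-table inputs from
which the rule metrics and odds-ratio arithmetic can be reconstructed
exactly (see :func:`reference_rules`).
"""

from __future__ import annotations

import pandas as pd

#: total discharge episodes in the cohort
COHORT_N = 169_959

#: comorbidity / thyroid item marginal counts (any diagnosis position)
ITEM_COUNTS = {
    "DM": 21_893,
    "HTN": 34_665,
    "Hyperthyroidism": 301,
    "Hypothyroidism": 1_802,
}

#: per cancer site: (episodes, with DM, with HTN); sites partition the cohort
SITE_TABLE = {
    "Pancreatic cancer": (5_514, 1_649, 1_552),
    "Bile duct cancer": (3_361, 763, 1_056),
    "Lung cancer": (21_227, 3_260, 5_541),
    "Gallbladder cancer": (1_989, 308, 531),
    "Small intestine cancer": (646, 100, 146),
    "Multiple myeloma": (1_894, 285, 496),
    "Kidney cancer": (2_895, 444, 854),
    "Colorectal cancer": (21_043, 2_829, 4_861),
    "Ureter cancer": (620, 91, 189),
    "Bladder cancer": (4_489, 643, 1_233),
    "Laryngeal cancer": (1_197, 153, 245),
    "Liver cancer": (19_924, 4_254, 4_534),
    "Stomach cancer": (22_198, 2_800, 4_854),
    "Prostate cancer": (5_509, 674, 1_477),
    "Anal cancer": (184, 22, 43),
    "Esophageal cancer": (2_224, 258, 490),
    "Other": (55_045, 3_360, 6_563),
}

#: demographic / clinical marginals: stratum -> {level: (n, n_dm, n_htn)}
BASELINE_TABLE = {
    "sex": {
        "male": (91_526, 14_357, 20_777),
        "female": (78_433, 7_536, 13_888),
    },
    "age_group": {
        "19-44": (24_561, 556, 657),
        "45-64": (75_738, 8_724, 12_227),
        "65-74": (43_762, 8_033, 13_085),
        "75+": (25_898, 4_580, 8_696),
    },
    "treatment_outcome": {
        "improved": (150_868, 19_032, 30_723),
        "not_improved": (8_191, 1_133, 1_705),
        "death": (10_311, 1_630, 2_112),
        "other": (589, 98, 125),
    },
    "surgery": {
        True: (69_202, 6_574, 12_802),
        False: (100_757, 15_319, 21_863),
    },
    "chemotherapy": {
        True: (19_345, 2_750, 3_872),
        False: (150_614, 19_143, 30_793),
    },
    "radiotherapy": {
        True: (719, 103, 151),
        False: (169_240, 21_790, 34_514),
    },
    "hyperthyroidism": {
        True: (301, 61, 79),
        False: (169_658, 21_832, 34_586),
    },
    "hypothyroidism": {
        True: (1_802, 307, 476),
        False: (168_157, 21_586, 34_189),
    },
}

#: joint episode counts for disease pairs (symmetric, frozenset keys)
PAIR_COUNTS = {
    frozenset({"DM", "HTN"}): 11_740,
    frozenset({"HTN", "Liver cancer"}): 4_534,
    frozenset({"DM", "Liver cancer"}): 4_254,
    frozenset({"HTN", "Lung cancer"}): 5_541,
    frozenset({"DM", "Lung cancer"}): 3_260,
    frozenset({"HTN", "Colorectal cancer"}): 4_861,
    frozenset({"DM", "Colorectal cancer"}): 2_829,
    frozenset({"HTN", "Stomach cancer"}): 4_854,
    frozenset({"DM", "Stomach cancer"}): 2_800,
}

#: joint episode counts for disease triples
TRIPLE_COUNTS = {
    frozenset({"DM", "HTN", "Liver cancer"}): 1_964,
    frozenset({"DM", "HTN", "Lung cancer"}): 1_813,
}

#: the 22 published rules, in published rank order: (antecedent, consequent)
PUBLISHED_RULE_ORDER = [
    (("DM",), "HTN"),
    (("HTN",), "DM"),
    (("Lung cancer",), "HTN"),
    (("HTN",), "Lung cancer"),
    (("Liver cancer",), "DM"),
    (("DM",), "Liver cancer"),
    (("HTN", "Liver cancer"), "DM"),
    (("Colorectal cancer",), "HTN"),
    (("HTN",), "Colorectal cancer"),
    (("Stomach cancer",), "HTN"),
    (("HTN",), "Stomach cancer"),
    (("Liver cancer",), "HTN"),
    (("HTN",), "Liver cancer"),
    (("DM", "Lung cancer"), "HTN"),
    (("HTN", "Lung cancer"), "DM"),
    (("DM", "Liver cancer"), "HTN"),
    (("Lung cancer",), "DM"),
    (("DM",), "Lung cancer"),
    (("Colorectal cancer",), "DM"),
    (("DM",), "Colorectal cancer"),
    (("DM", "HTN"), "Liver cancer"),
    (("DM", "HTN"), "Lung cancer"),
]

#: published logistic mortality models: subset -> term -> (B, SE, OR, lo, hi)
#: liver x hyperthyroidism is inestimable in the source (zero event cell)
MORTALITY_TABLE = {
    "All cancer": {
        "dm": (-0.086, 0.030, 0.917, 0.865, 0.973),
        "htn": (0.182, 0.027, 1.200, 1.137, 1.266),
        "hypothyroidism": (0.033, 0.101, 1.033, 0.849, 1.259),
        "hyperthyroidism": (0.568, 0.325, 1.765, 0.933, 3.340),
    },
    "Stomach cancer": {
        "dm": (-0.059, 0.097, 0.943, 0.780, 1.140),
        "htn": (0.402, 0.087, 1.495, 1.261, 1.772),
        "hypothyroidism": (-0.190, 0.355, 0.827, 0.412, 1.657),
        "hyperthyroidism": (0.629, 1.024, 1.876, 0.252, 13.966),
    },
    "Colorectal cancer": {
        "dm": (0.060, 0.104, 1.061, 0.865, 1.302),
        "htn": (0.182, 0.088, 1.199, 1.008, 1.426),
        "hypothyroidism": (-0.137, 0.399, 0.872, 0.399, 1.907),
        "hyperthyroidism": (0.236, 1.033, 1.266, 0.167, 9.588),
    },
    "Liver cancer": {
        "dm": (0.235, 0.065, 1.265, 1.113, 1.437),
        "htn": (0.217, 0.065, 1.242, 1.093, 1.411),
        "hypothyroidism": (-0.724, 0.236, 0.485, 0.305, 0.771),
    },
    "Lung cancer": {
        "dm": (-0.079, 0.066, 0.924, 0.812, 1.051),
        "htn": (0.239, 0.057, 1.270, 1.135, 1.421),
        "hypothyroidism": (-0.249, 0.242, 0.779, 0.485, 1.252),
        "hyperthyroidism": (0.011, 0.533, 1.011, 0.356, 2.872),
    },
}


def itemset_count(items: frozenset) -> int:
    """Episode count of a published itemset (size 1-3).

    Single items resolve through the comorbidity marginals or the site
    table; pairs and triples through the published joint counts.
    """
    items = frozenset(items)
    if len(items) == 1:
        (item,) = items
        if item in ITEM_COUNTS:
            return ITEM_COUNTS[item]
        if item in SITE_TABLE:
            return SITE_TABLE[item][0]
        raise KeyError(f"no published marginal count for {item!r}")
    if len(items) == 2:
        return PAIR_COUNTS[items]
    if len(items) == 3:
        return TRIPLE_COUNTS[items]
    raise KeyError(f"no published joint count for {sorted(items)}")


def reference_rules():
    """Reconstruct the 22 published rules from the printed counts.

    Returns a ranked list of :class:`comorbid_arm.arm.AssociationRule`
    whose metrics are recomputed (not transcribed) from the joint and
    marginal counts above.
    """
    from .arm import AssociationRule, compute_metrics, rank_rules

    rules = []
    for antecedent, consequent in PUBLISHED_RULE_ORDER:
        ante = frozenset(antecedent)
        joint = itemset_count(ante | {consequent})
        m = compute_metrics(
            count_ab=joint,
            count_a=itemset_count(ante),
            count_b=itemset_count(frozenset({consequent})),
            n=COHORT_N,
        )
        rules.append(
            AssociationRule(
                antecedent=ante,
                consequent=frozenset({consequent}),
                count=joint,
                support=m.support,
                confidence=m.confidence,
                lift=m.lift,
                is_score=m.is_score,
            )
        )
    return rank_rules(rules)


def baseline_frame() -> pd.DataFrame:
    """Demographic marginals as a tidy frame (stratifier, level, n, dm, htn)."""
    rows = []
    for strat, levels in BASELINE_TABLE.items():
        for level, (n, dm, htn) in levels.items():
            rows.append((strat, level, n, dm, htn))
    return pd.DataFrame(
        rows, columns=["stratifier", "level", "n", "n_dm", "n_htn"]
    )
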