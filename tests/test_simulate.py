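import math

import numpy as np
import pytest

from comorbid_arm.phenotyping import phenotype_cohort
from comorbid_arm.records import filter_cohort, write_cohort
from comorbid_arm.simulate import (
    SyntheticCohortConfig,
    calibrate_intercept,
    generate_cohort,
    plant_pairwise_joint,
)

PROFILE_COLUMNS = [
    "dm", "htn", "hyperthyroidism", "hypothyroidism", "surgery",
    "chemotherapy", "radiotherapy", "cancer_site", "died", "sex", "age_group",
]


def test_planted_joint_matches_target_lift():
    # the published DM-HTN rule: joint probability == its support 0.069
    p_ab = plant_pairwise_joint(0.129, 0.204, 2.629)
    assert p_ab == pytest.approx(0.0692, abs=5e-4)
    assert p_ab / (0.129 * 0.204) == pytest.approx(2.629)


def test_planted_joint_independence_is_product():
    assert plant_pairwise_joint(0.3, 0.4, 1.0) == pytest.approx(0.12)


def test_planted_joint_infeasible_lift_raises():
    # 3.0 * 0.5 * 0.5 = 0.75 > min(p_a, p_b) = 0.5
    with pytest.raises(ValueError, match="Frechet"):
        plant_pairwise_joint(0.5, 0.5, 3.0)
    with pytest.raises(ValueError):
        plant_pairwise_joint(0.0, 0.5, 1.0)


def test_default_config_is_feasible_and_sums_to_one():
    cfg = SyntheticCohortConfig()
    cfg.validate()
    assert sum(cfg.site_distribution.values()) == pytest.approx(1.0, abs=1e-9)


def test_zero_size_cohort():
    assert generate_cohort(SyntheticCohortConfig(n=0, seed=1)).n == 0


def test_same_seed_gives_identical_csv_bytes(tmp_path):
    cfg = SyntheticCohortConfig(n=400, seed=42)
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort(generate_cohort(cfg), a)
    write_cohort(generate_cohort(SyntheticCohortConfig(n=400, seed=42)), b)
    assert a.read_bytes() == b.read_bytes()
    c = tmp_path / "c.csv"
    write_cohort(generate_cohort(SyntheticCohortConfig(n=400, seed=43)), c)
    assert a.read_bytes() != c.read_bytes()


def test_generated_records_survive_the_cohort_filter():
    cohort = generate_cohort(SyntheticCohortConfig(n=500, seed=2))
    assert filter_cohort(cohort).n == cohort.n  # all adult, all malignant


def test_phenotyping_recovers_planted_truth_exactly():
    cohort, truth = generate_cohort(
        SyntheticCohortConfig(n=2000, seed=9), return_truth=True
    )
    profiles = phenotype_cohort(cohort)
    for col in PROFILE_COLUMNS:
        assert (profiles[col].to_numpy() == truth[col].to_numpy()).all(), col


def test_marginals_recovered_within_sampling_error():
    n = 20_000
    cfg = SyntheticCohortConfig(n=n, seed=123)
    _, truth = generate_cohort(cfg, return_truth=True)
    checks = {
        "dm": 21_893 / 169_959,
        "htn": 34_665 / 169_959,
        "surgery": cfg.p_surgery,
        "chemotherapy": cfg.p_chemotherapy,
    }
    for col, p in checks.items():
        se = math.sqrt(p * (1 - p) / n)
        assert abs(truth[col].mean() - p) < 3.5 * se, col
    assert truth["sex"].eq("male").mean() == pytest.approx(cfg.p_male, abs=0.015)


def test_site_conditional_prevalences_are_planted():
    _, truth = generate_cohort(
        SyntheticCohortConfig(n=60_000, seed=5), return_truth=True
    )
    liver = truth[truth["cancer_site"] == "Liver cancer"]
    # published liver-cancer DM prevalence 21.4%
    assert liver["dm"].mean() == pytest.approx(0.214, abs=0.02)


def test_calibrated_intercept_hits_target_death_rate():
    cfg = SyntheticCohortConfig(n=30_000, seed=77)
    b0 = calibrate_intercept(cfg)
    assert -6 < b0 < 0
    _, truth = generate_cohort(cfg, return_truth=True)
    # mean of the model death probabilities estimates the calibrated
    # expectation with only covariate-sampling noise
    assert truth["death_prob"].mean() == pytest.approx(
        cfg.baseline_death_rate, abs=0.003
    )
    assert truth["died"].mean() == pytest.approx(cfg.baseline_death_rate, abs=0.006)


def test_flat_marginals_mode_plants_global_lift():
    cfg = SyntheticCohortConfig(
        n=50_000, seed=31,
        site_conditional_prevalences=None,
        comorbidity_marginals={
            "dm": 0.129, "htn": 0.204,
            "hyperthyroidism": 0.002, "hypothyroidism": 0.011,
        },
    )
    _, truth = generate_cohort(cfg, return_truth=True)
    p_ab = (truth["dm"] & truth["htn"]).mean()
    lift = p_ab / (truth["dm"].mean() * truth["htn"].mean())
    assert lift == pytest.approx(2.629, rel=0.08)


def test_age_years_consistent_with_age_group():
    _, truth = generate_cohort(SyntheticCohortConfig(n=500, seed=4),
                               return_truth=True)
    cohort = generate_cohort(SyntheticCohortConfig(n=500, seed=4))
    bounds = {"19-44": (19, 44), "45-64": (45, 64),
              "65-74": (65, 74), "75+": (75, 200)}
    for rec, group in zip(cohort.records, truth["age_group"]):
        lo, hi = bounds[group]
        assert lo <= rec.age_years <= hi
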