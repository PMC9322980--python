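"""Synthetic discharge-cohort generator.

Emulates the statistical structure of the KNHDIS adult cancer cohort so
the whole pipeline is testable without the access-restricted microdata:

* cancer-site distribution and per-site DM/HTN prevalences matching the
  published cross-tabulations;
* a planted DM-HTN dependence expressed as a target lift, realized
  exactly through an explicit 2x2 joint (p11 = lift * p_dm * p_htn,
  feasibility-checked against the Frechet bounds);
* independent thyroid-disease and treatment flags at the published rates;
* in-hospital death drawn from a logistic model whose exposure
  coefficients default to the published all-cancer estimates, with the
  intercept calibrated deterministically so the expected death rate
  equals the configured 6.1%.

Records are emitted as ICD codes (principal site code, secondary
comorbidity codes, ICD-9-CM procedure codes), not as flags, so the
phenotyping stage is exercised end to end; phenotyping recovers the
planted flags exactly by construction.

All randomness flows through one seeded ``numpy`` Generator with a fixed,
documented column order of vectorized draws — adding a new field appends
a new draw block, leaving existing columns unchanged for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import datasets
from .records import Cohort, DischargeRecord

__all__ = [
    "SyntheticCohortConfig",
    "plant_pairwise_joint",
    "calibrate_intercept",
    "generate_cohort",
]


def plant_pairwise_joint(p_a: float, p_b: float, target_lift: float) -> float:
    """Joint probability realizing a target lift for two binary traits.

    ``p_ab = lift * p_a * p_b``, validated against the Frechet bounds
    ``max(0, p_a + p_b - 1) <= p_ab <= min(p_a, p_b)``.
    """
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError("marginals must be in (0, 1)")
    if target_lift <= 0:
        raise ValueError("lift must be positive")
    p_ab = target_lift * p_a * p_b
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    if not (lo - 1e-12 <= p_ab <= hi + 1e-12):
        raise ValueError(
            f"lift {target_lift} infeasible for marginals ({p_a}, {p_b}): "
            f"joint {p_ab:.4f} outside Frechet bounds [{lo:.4f}, {hi:.4f}]"
        )
    return float(min(max(p_ab, lo), hi))


def _default_site_distribution() -> dict[str, float]:
    return {
        site: total / datasets.COHORT_N
        for site, (total, _, _) in datasets.SITE_TABLE.items()
    }


def _default_site_conditional() -> dict[str, tuple[float, float]]:
    return {
        site: (dm / total, htn / total)
        for site, (total, dm, htn) in datasets.SITE_TABLE.items()
    }


def _default_marginals() -> dict[str, float]:
    n = datasets.COHORT_N
    return {
        "dm": datasets.ITEM_COUNTS["DM"] / n,
        "htn": datasets.ITEM_COUNTS["HTN"] / n,
        "hyperthyroidism": datasets.ITEM_COUNTS["Hyperthyroidism"] / n,
        "hypothyroidism": datasets.ITEM_COUNTS["Hypothyroidism"] / n,
    }


def _default_mortality_coefficients() -> dict[str, float]:
    # exposures: published all-cancer estimates; controls: chosen plausible
    # effects (see docs/methods.md); intercept None => calibrated
    return {
        "const": None,
        "dm": -0.086,
        "htn": 0.182,
        "hypothyroidism": 0.033,
        "hyperthyroidism": 0.568,
        "sex_male": 0.30,
        "age_45_64": 0.60,
        "age_65_74": 0.90,
        "age_75_plus": 1.30,
        "surgery": -0.90,
        "chemotherapy": 0.15,
        "radiotherapy": 0.10,
    }


#: representative emitted code per condition/site; mixes dotted and bare
#: category forms so range matching is exercised on both
DEFAULT_SITE_CODES = {
    "Stomach cancer": "C16.0",
    "Colorectal cancer": "C18.9",
    "Liver cancer": "C22.0",
    "Lung cancer": "C34.9",
    "Pancreatic cancer": "C25.9",
    "Bile duct cancer": "C24.0",
    "Gallbladder cancer": "C23",
    "Small intestine cancer": "C17.9",
    "Multiple myeloma": "C90.0",
    "Kidney cancer": "C64",
    "Ureter cancer": "C66",
    "Bladder cancer": "C67.9",
    "Laryngeal cancer": "C32.9",
    "Prostate cancer": "C61",
    "Anal cancer": "C21.0",
    "Esophageal cancer": "C15.9",
    "Other": "C80",
}

DEFAULT_CONDITION_CODES = {
    "dm": "E11.9",
    "htn": "I10",
    "hyperthyroidism": "E05.0",
    "hypothyroidism": "E03.9",
}


@dataclass
class SyntheticCohortConfig:
    """Generator configuration; defaults reproduce the published cohort moments."""

    n: int = 170_000
    seed: int = 0
    site_distribution: dict = field(default_factory=_default_site_distribution)
    comorbidity_marginals: dict = field(default_factory=_default_marginals)
    #: per-site (p_dm, p_htn); None => flat marginals for every site
    site_conditional_prevalences: dict | None = field(
        default_factory=_default_site_conditional
    )
    #: target lift for the planted DM-HTN dependence (within-site when
    #: site-conditional prevalences are active)
    dm_htn_lift: float = 2.629
    mortality_coefficients: dict = field(
        default_factory=_default_mortality_coefficients
    )
    baseline_death_rate: float = 10_311 / 169_959  # 6.1%
    p_male: float = 91_526 / 169_959  # 53.9%
    age_group_probs: tuple = (
        24_561 / 169_959, 75_738 / 169_959, 43_762 / 169_959, 25_898 / 169_959,
    )
    p_surgery: float = 69_202 / 169_959
    p_chemotherapy: float = 19_345 / 169_959
    p_radiotherapy: float = 719 / 169_959
    #: survivor outcome split (improved, not improved, other), renormalized
    survivor_outcome_probs: tuple = (150_868, 8_191, 589)
    insurance_probs: dict = field(
        default_factory=lambda: {
            "national_health": 0.955, "medicaid_1": 0.030,
            "medicaid_2": 0.010, "other": 0.005,
        }
    )
    admission_probs: dict = field(
        default_factory=lambda: {"outpatient": 0.60, "emergency": 0.25, "other": 0.15}
    )
    site_codes: dict = field(default_factory=lambda: dict(DEFAULT_SITE_CODES))
    condition_codes: dict = field(default_factory=lambda: dict(DEFAULT_CONDITION_CODES))

    def validate(self) -> None:
        probs = np.array(list(self.site_distribution.values()))
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"site distribution sums to {probs.sum()}, not 1")
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("site probabilities must be in [0, 1]")
        for site, (p_dm, p_htn) in self._site_prevalences().items():
            plant_pairwise_joint(p_dm, p_htn, self.dm_htn_lift)  # feasibility
        for site in self.site_distribution:
            if site not in self.site_codes:
                raise ValueError(f"no emitted code configured for site {site!r}")

    def _site_prevalences(self) -> dict[str, tuple[float, float]]:
        if self.site_conditional_prevalences is not None:
            return {s: tuple(v) for s, v in self.site_conditional_prevalences.items()}
        flat = (self.comorbidity_marginals["dm"], self.comorbidity_marginals["htn"])
        return {site: flat for site in self.site_distribution}

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortConfig":
        cfg = cls()
        for key, value in d.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown simulate config key {key!r}")
            setattr(cfg, key, value)
        return cfg


def _covariate_blocks(config: SyntheticCohortConfig):
    """(linear-predictor offsets, probabilities) per independent block."""
    b = config.mortality_coefficients
    blocks = [
        (np.array([b["sex_male"], 0.0]), np.array([config.p_male, 1 - config.p_male])),
        (
            np.array([0.0, b["age_45_64"], b["age_65_74"], b["age_75_plus"]]),
            np.array(config.age_group_probs),
        ),
        (np.array([b["surgery"], 0.0]),
         np.array([config.p_surgery, 1 - config.p_surgery])),
        (np.array([b["chemotherapy"], 0.0]),
         np.array([config.p_chemotherapy, 1 - config.p_chemotherapy])),
        (np.array([b["radiotherapy"], 0.0]),
         np.array([config.p_radiotherapy, 1 - config.p_radiotherapy])),
    ]
    for flag in ("hyperthyroidism", "hypothyroidism"):
        p = config.comorbidity_marginals[flag]
        blocks.append((np.array([b[flag], 0.0]), np.array([p, 1 - p])))
    # joint (site, dm, htn) block
    lps, probs = [], []
    for site, w in config.site_distribution.items():
        p_dm, p_htn = config._site_prevalences()[site]
        p11 = plant_pairwise_joint(p_dm, p_htn, config.dm_htn_lift)
        cells = [
            (b["dm"] + b["htn"], p11),
            (b["dm"], p_dm - p11),
            (b["htn"], p_htn - p11),
            (0.0, 1 - p_dm - p_htn + p11),
        ]
        for lp, p in cells:
            lps.append(lp)
            probs.append(w * p)
    blocks.append((np.array(lps), np.array(probs)))
    return blocks


def calibrate_intercept(config: SyntheticCohortConfig) -> float:
    """Intercept making the expected death rate equal the configured one.

    The covariates are discrete with an explicitly known joint law
    (independent blocks), so E[expit(b0 + lp)] is enumerated exactly and
    b0 solved by root finding — fully deterministic.
    """
    lp, pr = np.array([0.0]), np.array([1.0])
    for lps, probs in _covariate_blocks(config):
        lp = np.add.outer(lp, lps).ravel()
        pr = np.multiply.outer(pr, probs).ravel()
        keep = pr > 1e-15  # prune negligible mass to bound the grid
        lp, pr = lp[keep], pr[keep]

    target = config.baseline_death_rate

    def deficit(b0):
        return float(pr @ expit(b0 + lp)) - target

    guess = float(logit(target) - pr @ lp)
    return float(brentq(deficit, guess - 6.0, guess + 6.0, xtol=1e-12))


def _categorical(rng, probs: np.ndarray, n: int) -> np.ndarray:
    """Inverse-CDF categorical draw (stable under fixed seed)."""
    edges = np.cumsum(probs)
    edges[-1] = max(edges[-1], 1.0)
    return np.searchsorted(edges, rng.random(n), side="right")


def generate_cohort(config: SyntheticCohortConfig, return_truth: bool = False):
    """Draw a synthetic cohort of discharge records.

    With ``return_truth=True`` also returns a DataFrame of the planted
    per-record flags (the generating truth), which phenotyping must
    recover exactly.
    """
    import pandas as pd

    config.validate()
    n = int(config.n)
    rng = np.random.default_rng(config.seed)
    b = dict(config.mortality_coefficients)
    if b.get("const") is None:
        b["const"] = calibrate_intercept(config)

    if n == 0:
        cohort = Cohort([])
        if return_truth:
            return cohort, pd.DataFrame()
        return cohort

    # draw blocks in fixed order; each block is one vectorized draw
    sex_male = rng.random(n) < config.p_male
    age_idx = _categorical(rng, np.array(config.age_group_probs), n)
    age_bounds = np.array([(19, 44), (45, 64), (65, 74), (75, 94)])
    lo, hi = age_bounds[age_idx, 0], age_bounds[age_idx, 1]
    age_years = lo + np.floor(rng.random(n) * (hi - lo + 1)).astype(int)
    ins_labels = list(config.insurance_probs)
    insurance = _categorical(rng, np.array(list(config.insurance_probs.values())), n)
    adm_labels = list(config.admission_probs)
    admission = _categorical(rng, np.array(list(config.admission_probs.values())), n)

    site_labels = list(config.site_distribution)
    site_idx = _categorical(
        rng, np.array(list(config.site_distribution.values())), n
    )
    # DM/HTN from the per-site planted 2x2 joint
    prevs = config._site_prevalences()
    cell_probs = np.zeros((len(site_labels), 3))
    for j, site in enumerate(site_labels):
        p_dm, p_htn = prevs[site]
        p11 = plant_pairwise_joint(p_dm, p_htn, config.dm_htn_lift)
        cell_probs[j] = (p11, p11 + (p_dm - p11), p11 + (p_dm - p11) + (p_htn - p11))
    u = rng.random(n)
    cp = cell_probs[site_idx]
    cell = np.select(
        [u < cp[:, 0], u < cp[:, 1], u < cp[:, 2]], [0, 1, 2], default=3
    )
    dm = cell <= 1
    htn = (cell == 0) | (cell == 2)

    hyper = rng.random(n) < config.comorbidity_marginals["hyperthyroidism"]
    hypo = rng.random(n) < config.comorbidity_marginals["hypothyroidism"]
    surgery = rng.random(n) < config.p_surgery
    chemo = rng.random(n) < config.p_chemotherapy
    radio = rng.random(n) < config.p_radiotherapy

    lp = (
        b["const"]
        + b["dm"] * dm
        + b["htn"] * htn
        + b["hypothyroidism"] * hypo
        + b["hyperthyroidism"] * hyper
        + b["sex_male"] * sex_male
        + b["age_45_64"] * (age_idx == 1)
        + b["age_65_74"] * (age_idx == 2)
        + b["age_75_plus"] * (age_idx == 3)
        + b["surgery"] * surgery
        + b["chemotherapy"] * chemo
        + b["radiotherapy"] * radio
    )
    death_p = expit(lp)
    died = rng.random(n) < death_p
    surv = np.array(config.survivor_outcome_probs, dtype=float)
    surv_idx = _categorical(rng, surv / surv.sum(), n)
    surv_labels = ["improved", "not_improved", "other"]

    age_group_labels = ["19-44", "45-64", "65-74", "75+"]
    records = []
    ccode = config.condition_codes
    for i in range(n):
        secondary = []
        if dm[i]:
            secondary.append(ccode["dm"])
        if htn[i]:
            secondary.append(ccode["htn"])
        if hyper[i]:
            secondary.append(ccode["hyperthyroidism"])
        if hypo[i]:
            secondary.append(ccode["hypothyroidism"])
        procedures = []
        if chemo[i]:
            procedures.append("99.25")
        if radio[i]:
            procedures.append("92.24")
        records.append(
            DischargeRecord(
                record_id=f"R{i:07d}",
                sex="male" if sex_male[i] else "female",
                age_years=int(age_years[i]),
                insurance_type=ins_labels[insurance[i]],
                admission_route=adm_labels[admission[i]],
                treatment_outcome="death" if died[i] else surv_labels[surv_idx[i]],
                principal_dx=config.site_codes[site_labels[site_idx[i]]],
                secondary_dx=tuple(secondary),
                procedure_codes=tuple(procedures),
                main_surgery_code="S001" if surgery[i] else None,
            )
        )
    cohort = Cohort(records)
    if not return_truth:
        return cohort
    truth = pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "dm": dm,
            "htn": htn,
            "hyperthyroidism": hyper,
            "hypothyroidism": hypo,
            "surgery": surgery,
            "chemotherapy": chemo,
            "radiotherapy": radio,
            "cancer_site": [site_labels[j] for j in site_idx],
            "died": died,
            "sex": np.where(sex_male, "male", "female"),
            "age_group": [age_group_labels[j] for j in age_idx],
            "death_prob": death_p,
        }
    )
    return cohort, truth
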