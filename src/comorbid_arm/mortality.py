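"""Logistic models of in-hospital death on comorbidity exposures.

The outcome is the death indicator of the discharge episode. Exposures are
the four comorbidity flags (DM, HTN, hypothyroidism, hyperthyroidism);
controls are sex, the four-level age group (reference 19-44), surgery,
chemotherapy and radiotherapy. Fits are maximum-likelihood logistic
regressions (Newton/IRLS); effects are reported as odds ratios with Wald
95% confidence intervals, OR = exp(B), CI = exp(B ± 1.96·SE).

Terms that are constant in a subset, or perfectly predictive of the
outcome (e.g. a rare exposure with zero deaths — quasi-separation), are
dropped with a recorded reason rather than reported with exploded
standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .stats import round_half_up

__all__ = [
    "LogisticFit",
    "EXPOSURE_TERMS",
    "CONTROL_TERMS",
    "build_design",
    "fit_logistic",
    "odds_ratio_report",
    "wald_or_ci",
    "forest_plot_data",
    "fit_mortality_models",
]

EXPOSURE_TERMS = ["dm", "htn", "hypothyroidism", "hyperthyroidism"]
CONTROL_TERMS = [
    "sex_male",
    "age_45_64",
    "age_65_74",
    "age_75_plus",
    "surgery",
    "chemotherapy",
    "radiotherapy",
]

_AGE_DUMMIES = {"45-64": "age_45_64", "65-74": "age_65_74", "75+": "age_75_plus"}

_Z95 = 1.96  # normal quantile used for all reported Wald intervals


@dataclass
class LogisticFit:
    """Converged ML logistic fit with Wald odds-ratio reporting."""

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    n_used: int
    converged: bool
    llf: float
    llnull: float
    dropped_terms: list[tuple[str, str]] = field(default_factory=list)
    separation_flags: list[str] = field(default_factory=list)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.params - _Z95 * self.bse)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.params + _Z95 * self.bse)

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(self.params / self.bse)
        return 2.0 * norm.sf(z)


def build_design(
    profiles: pd.DataFrame,
    subset: str | None = None,
    include_surgery: bool = True,
):
    """Design matrix + outcome for one mortality model.

    ``subset`` restricts to one cancer-site label (None = full cohort).
    Zero-variance terms and quasi-separated binary terms are removed and
    recorded in the returned ``dropped`` list of (term, reason).
    """
    df = profiles if subset is None else profiles[profiles["cancer_site"] == subset]
    if len(df) == 0:
        raise ValueError(f"no records for subset {subset!r}")
    y = df["died"].astype(int).reset_index(drop=True)
    X = pd.DataFrame({"const": 1.0}, index=range(len(df)))
    cols = {}
    for term in EXPOSURE_TERMS:
        cols[term] = df[term].astype(int).to_numpy()
    cols["sex_male"] = (df["sex"] == "male").astype(int).to_numpy()
    for level, name in _AGE_DUMMIES.items():
        cols[name] = (df["age_group"] == level).astype(int).to_numpy()
    for term in ("surgery", "chemotherapy", "radiotherapy"):
        if term == "surgery" and not include_surgery:
            continue
        cols[term] = df[term].astype(int).to_numpy()

    dropped = []
    yv = y.to_numpy()
    for term, v in cols.items():
        if v.min() == v.max():
            dropped.append((term, "zero variance in subset"))
            continue
        separated = False
        for side, level in (("exposed", 1), ("unexposed", 0)):
            group = yv[v == level]
            if group.sum() == 0 or group.sum() == group.size:
                dropped.append(
                    (term, f"quasi-separation: outcome constant among {side}")
                )
                separated = True
                break
        if separated:
            continue
        X[term] = v.astype(float)
    return X, y, dropped


def fit_logistic(X: pd.DataFrame, y: pd.Series, dropped=None) -> LogisticFit:
    """Newton/IRLS maximum-likelihood fit with Wald standard errors.

    Standard errors come from the inverse observed information at the
    optimum. Non-convergence and residual separation (runaway
    coefficients) are flagged on the fit, never silently reported.
    """
    yv = np.asarray(y)
    if yv.sum() == 0 or yv.sum() == len(yv):
        raise ValueError("degenerate outcome: needs at least one event and one non-event")
    model = sm.Logit(yv, np.asarray(X, dtype=float))
    res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    flags = []
    if not res.mle_retvals.get("converged", False):
        flags.append("did not converge within 100 Newton iterations")
    big = [t for t, b in zip(X.columns, res.params) if abs(b) > 15]
    if big:
        flags.append(f"possible separation: runaway coefficient(s) {big}")
    return LogisticFit(
        terms=list(X.columns),
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        n_used=int(len(yv)),
        converged=bool(res.mle_retvals.get("converged", False)),
        llf=float(res.llf),
        llnull=float(res.llnull),
        dropped_terms=list(dropped or []),
        separation_flags=flags,
    )


def wald_or_ci(b: float, se: float) -> tuple[float, float, float]:
    """(OR, ci_low, ci_high) = exp(B), exp(B ± 1.96·SE)."""
    with np.errstate(over="ignore"):  # inf is a legitimate report for a flagged fit
        return (
            float(np.exp(b)),
            float(np.exp(b - _Z95 * se)),
            float(np.exp(b + _Z95 * se)),
        )


def odds_ratio_report(fit: LogisticFit, terms: list[str] | None = None) -> pd.DataFrame:
    """Report rows (B, SE, OR, 95% CI, Wald p) rounded half-up to 3 dp."""
    rows = []
    wanted = terms if terms is not None else [t for t in fit.terms if t != "const"]
    for term in wanted:
        if term not in fit.terms:
            continue
        i = fit.terms.index(term)
        or_, lo, hi = wald_or_ci(fit.params[i], fit.bse[i])
        rows.append(
            {
                "term": term,
                "B": round_half_up(fit.params[i], 3),
                "SE": round_half_up(fit.bse[i], 3),
                "OR": round_half_up(or_, 3),
                "ci_low": round_half_up(lo, 3),
                "ci_high": round_half_up(hi, 3),
                "p": round_half_up(fit.p_values[i], 3),
            }
        )
    return pd.DataFrame(rows, columns=["term", "B", "SE", "OR", "ci_low", "ci_high", "p"])


def fit_mortality_models(
    profiles: pd.DataFrame,
    subsets=("All cancer", "Stomach cancer", "Colorectal cancer",
             "Liver cancer", "Lung cancer"),
    include_surgery: bool = True,
) -> dict[str, LogisticFit]:
    """Fit the full-cohort model and one model per major cancer site."""
    fits = {}
    for label in subsets:
        subset = None if label == "All cancer" else label
        X, y, dropped = build_design(profiles, subset, include_surgery)
        fits[label] = fit_logistic(X, y, dropped)
    return fits


def forest_plot_data(fits: dict[str, LogisticFit]) -> pd.DataFrame:
    """Long-format (cancer, term, OR, ci_low, ci_high) for forest plotting.

    Exposure terms dropped from a subset model (inestimable) are omitted
    and listed in the fit's ``dropped_terms`` instead.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    for cancer, fit in fits.items():
        for term in EXPOSURE_TERMS:
            if term not in fit.terms:
                continue
            i = fit.terms.index(term)
            or_, lo, hi = wald_or_ci(fit.params[i], fit.bse[i])
            rows.append(
                {"cancer": cancer, "term": term, "OR": or_,
                 "ci_low": lo, "ci_high": hi, "p": fit.p_values[i]}
            )
    return pd.DataFrame(rows, columns=["cancer", "term", "OR", "ci_low", "ci_high", "p"])


def render_forest_plot(plot_data: pd.DataFrame, path) -> None:
    """Static forest plot of odds ratios (log scale) per cancer and term."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = plot_data.reset_index(drop=True)
    labels = [f"{r.cancer}: {r.term}" for r in data.itertuples()]
    ypos = np.arange(len(data))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * max(len(data), 4) + 1.5))
    ax.errorbar(
        data["OR"], ypos,
        xerr=[data["OR"] - data["ci_low"], data["ci_high"] - data["OR"]],
        fmt="s", color="black", ecolor="gray", capsize=3, markersize=4,
    )
    ax.axvline(1.0, color="red", linestyle="--", linewidth=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xscale("log")
    ax.set_xlabel("Odds ratio of in-hospital death (log scale, Wald 95% CI)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
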