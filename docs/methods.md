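# Methods

## Cohort model

The unit of analysis is the **discharge episode**, not the person: the
emulated registry (KNHDIS) carries no identifier linking repeat admissions,
so episodes are treated as independent observations throughout. The cohort
filter retains adults (age ≥ 19 at discharge) whose *principal* diagnosis is
a malignant neoplasm (ICD-10 C00–C97). Filtering is total and idempotent;
dropped records are counted by reason (under-age, non-malignant principal,
malformed code) and logged, never silently discarded. Reading is strict by
default — any invalid row aborts with row numbers — with an explicit
permissive mode that drops and logs.

## Phenotyping

Codes are normalized (uppercase, dots and whitespace stripped) and matched
by inclusive range membership with prefix semantics at both endpoints: a
bare-category endpoint covers all its subdivisions (`C33`–`C34.9` contains
`C34.9`; `C18.0`–`C19` contains `C19.9`), and a bare-category code falls
inside a subdivided range (`E11` lies in `E11.0`–`E14.9`).

Operational definitions:

| label | codes | positions searched |
|---|---|---|
| diabetes mellitus | E11.0–E14.9 | any diagnosis |
| hypertension | I10 | any diagnosis |
| hyperthyroidism | E05.0–E05.9 | any diagnosis |
| hypothyroidism | E02–E03.9, E89.0 | any diagnosis |
| chemotherapy | proc 99.25 or dx Z51.1 | procedures / diagnoses |
| radiotherapy | proc 92.21–92.27, 92.29 | procedures |
| surgery | main surgery code non-null | — |
| cancer site | site ranges below | principal only |

Comorbidities are accepted from **any** diagnosis position: the principal
diagnosis is a malignancy by cohort construction, so chronic disease can only
appear as a secondary code. Chemotherapy is accepted from either its
procedure code or its session diagnosis, since registries record it both
ways. The radiotherapy definition is read as the contiguous block
92.21–92.27 plus the isolated 92.29 (the only internally consistent parse of
the range as published).

The cancer site comes from the principal diagnosis alone and is a partition:
stomach C16.0–C16.9, colorectal C18.0–C19, liver C22.0–C22.9, lung
C33–C34.9 follow the registry's stated definitions; the thirteen remaining
sites are not fixed by any published operational definition and default to
the conventional ICD-10 site categories (esophagus C15, small intestine C17,
anus C21, gallbladder C23, bile duct C24, pancreas C25, larynx C32, prostate
C61, kidney C64, ureter C66, bladder C67, multiple myeloma C90). These
defaults are assumptions, ship in a YAML-overridable code map, and are
validated for mutual disjointness at load time. Two deliberate choices keep
the partition consistent: intrahepatic bile-duct cancer (C22.1) stays with
liver because the liver definition spans all of C22, so the bile-duct label
is restricted to C24; malignancies outside every named range get the
residual label "Other". Age groups are 19–44 (reference), 45–64, 65–74, ≥75.

## Prevalence tables and tests

Prevalence rows report (n, %) per stratum plus a Total row; percentages are
rounded half-up to one decimal, the convention of the reported tables (all
internal computation is full precision; rounding happens only at the report
boundary, here and in the rule and OR tables). Group comparisons use the
plain Pearson χ² test — no continuity correction, appropriate at registry
scale — via `scipy.stats.chi2_contingency`, with Bonferroni adjustment
p_adj = min(1, m·p_raw). Which comparisons share a correction family is a
reporting convention, not a property of the data, so the family size m is an
explicit argument recorded in every result object, and raw p-values are
always reported alongside adjusted ones.

## Rule mining

Transactions are per-episode label sets over the four comorbidity items plus
the cancer-site item ("Other" participates by default and can be excluded).
Episodes with no item still count toward the denominator N — support is a
fraction of all study participants.

The miner is a hand-written level-wise Apriori: level-k candidates join
frequent (k−1)-itemsets sharing a (k−2)-prefix and are pruned unless every
(k−1)-subset is frequent; counting is vectorized over a boolean incidence
matrix. All thresholds are strict inequalities: itemsets need support
> 0.01, rules need confidence > 0.1 ("minimum reliability" is interpreted as
minimum confidence, the slot it occupies) and lift > 1 (rules at exact
independence are excluded). Consequents are single items by default
(configurable), matching the published rule set. The suite proves exact
equivalence — itemsets, rules, and all four metrics to 1e-12 — against
brute-force subset enumeration on hundreds of random instances.

IS is implemented as √(support·lift). The source's formula display reads as
a plain product, but every published IS value matches the square root
(√(0.069·2.629) = 0.426, whereas the product would give 0.181), which is
also the standard cosine interest-support measure; the square root is
therefore taken as the intended definition.

Ranking is a deterministic total order: IS descending, then joint count
descending, then confidence descending, then rule label. The confidence
tie-break is what orders each bidirectional pair (both directions share
support, lift, IS and count): the higher-confidence direction comes first,
reproducing the published 1→22 ordering exactly.

## Mortality models

Logistic regression of the death indicator (treatment outcome "death" vs.
all others) on the four comorbidity exposures with controls sex, age group,
surgery, chemotherapy, radiotherapy — fit per cancer site (stomach,
colorectal, liver, lung) and on the full cohort. The full-cohort model does
not adjust for cancer site by default (no site covariates appear in any
reported model); subset models condition on site by construction. Surgery is
included as a control by default with a switch to drop it (the reported
control sets differ between the table footnote, which lists it, and the
text, which does not; the footnote is followed).

Fitting is Newton-type maximum likelihood (statsmodels `Logit`, tolerance
1e-10, 100 iterations), standard errors from the inverse observed
information, Wald p = 2·Φ(−|B/SE|), and 95% CI = exp(B ± 1.96·SE). Before
fitting, terms that are constant in the subset, or whose exposed or
unexposed group has a constant outcome (quasi-separation — e.g. a rare
exposure with zero deaths), are dropped with a recorded reason rather than
reported with exploded standard errors; residual separation (runaway
coefficients) and non-convergence are flagged on the fit object. Degenerate
outcomes (no events, or all events) are an error.

## Synthetic cohort generator

The generator emulates exactly the moments the analysis consumes, and
no more:

* **Site distribution** — the published share of each of the 17 site labels.
* **Comorbidity structure** — per-site DM and HTN prevalences from the
  published cross-tabulation, with the DM–HTN dependence planted *exactly*
  through an explicit 2×2 joint: p₁₁ = lift·p_DM·p_HTN, checked against the
  Fréchet bounds [max(0, p_a+p_b−1), min(p_a, p_b)] and refused if
  infeasible. The default within-site lift is 2.629, the published
  cohort-level value; because DM and HTN prevalences covary across sites,
  the emergent cohort-level lift under site-conditional defaults is slightly
  higher (≈ 2.9). Setting `site_conditional_prevalences=None` plants the
  lift at the cohort level exactly (flat marginals DM 0.129 / HTN 0.204),
  which is the configuration used when validating lift recovery. Thyroid
  flags are independent at their marginal rates (hyper 0.18%, hypo 1.1%).
* **Treatment flags** — independent Bernoulli at the published rates
  (surgery 40.7%, chemotherapy 11.4%, radiotherapy 0.4%).
* **Mortality** — death drawn from the logistic model above. Exposure
  coefficients default to the published full-cohort estimates (DM −0.086,
  HTN 0.182, hypothyroidism 0.033, hyperthyroidism 0.568). Control effects
  are not published and default to plausible values chosen once: sex_male
  0.30, age 0.60/0.90/1.30 across the three non-reference groups, surgery
  −0.90 (resectable disease marks better prognosis), chemotherapy 0.15,
  radiotherapy 0.10. The intercept is calibrated deterministically — the
  covariates are discrete with a known joint law, so E[expit(b₀ + x'b)] is
  enumerated exactly and b₀ solved by Brent's method — to hit the published
  6.1% in-hospital death rate. Survivors split improved / not improved /
  other at the published proportions.
* **Demographics** — sex 53.9% male; age groups 14.5/44.6/25.7/15.2%;
  integer age uniform within group (75+ capped at 94). Insurance type and
  admission route are carried as fields with assumed splits (95.5% national
  health; 60/25/15% outpatient/emergency/other) — they stratify nothing in
  the shipped analyses.

Records are emitted as **codes**, not flags: one representative ICD-10 code
per site and condition (mixing dotted and bare-category forms so range
matching is exercised on both), procedure codes 99.25/92.24, and a surgery
code — phenotyping must invert the emission exactly, and the suite asserts
that round trip per record. All draws flow through one seeded numpy
Generator in a fixed, documented block order (sex, age group, age, insurance,
admission, site, DM/HTN cell, thyroid, treatments, death, survivor outcome);
identical config and seed give byte-identical CSV output.

What the generator does **not** model: person-level correlation across
episodes, secular trends over the survey years, hospital strata or sampling
weights, dependence between treatments and comorbidities, site-specific
mortality beyond what the comorbidity and control coefficients induce, and
any higher-order dependence beyond the planted pairwise joint. Passing tests
therefore demonstrate correctness of the *pipeline* under the stated
generating model, not fidelity of any specific real-world estimate.

## Numerical conventions

* Reported values round half-up (ties away from zero): 3 decimals for rule
  metrics and regression tables, 1 decimal for percentages; `inf` from a
  flagged degenerate fit passes through unrounded.
* Metric identities hold to 1e-12: lift and IS symmetric in both directions;
  √(support·lift) ≡ support/√(P(A)P(B)).
* Reconstructing OR/CI from coefficients printed at 3 decimals is exact only
  to the propagated input rounding: the unrounded (B, SE) lie within
  ±0.0005, so the reconstruction can differ multiplicatively by up to
  exp(0.0005 + 1.96·0.0005) ≈ 0.15%; comparisons against printed regression
  tables use exactly that bound.
* Problem sizes used by the validation suite, chosen to estimate each
  quantity well past its tolerance: 200,000 episodes for lift recovery
  (binomial SE of the joint support ≈ 0.0006, under 1% of the planted
  effect), 40 cohorts of 50,000 for coefficient recovery (each term
  within 3 estimated SEs on ≥ 95% of cohorts), 200 random instances for
  miner-vs-enumeration equivalence.

## Known limitations

* The emulated registry's true joint distribution over all 17 sites and 4
  comorbidities is unknowable from published marginals; only the documented
  moments are matched.
* Separation handling drops terms rather than applying a penalized (Firth)
  fallback; inestimable cells are reported as omissions, mirroring how the
  source tables print "-".
* No Fisher exact tests, standardized rates, FP-Growth variants, or
  statistical significance testing of individual rules.
* The code-range matcher validates lexical shape, not membership in any
  official ICD-10 release, and does not reconcile code-system revisions
  across survey years.
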