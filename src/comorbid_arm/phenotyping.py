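"""ICD-10 / ICD-9-CM code normalization, range membership and phenotyping.

Each discharge episode is mapped to a :class:`PhenotypeProfile`: boolean
comorbidity flags (diabetes mellitus, hypertension, hyper-/hypothyroidism),
treatment flags (surgery, chemotherapy, radiotherapy), a single cancer-site
label derived from the principal diagnosis, the death indicator and the
demographic grouping used downstream.

Code matching is by *range membership* over normalized codes (uppercase,
dots stripped), with prefix semantics at both endpoints: a bare category
endpoint such as ``C33`` covers all its subdivisions, and a bare-category
code such as ``E11`` falls inside ``E11.0-E14.9``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

__all__ = [
    "CodeError",
    "CodeInterval",
    "CodeMap",
    "PhenotypeProfile",
    "normalize_code",
    "code_in_range",
    "default_code_map",
    "age_group_of",
    "phenotype_record",
    "phenotype_cohort",
    "AGE_GROUPS",
    "CANCER_RANGE",
]


class CodeError(ValueError):
    """Raised for malformed codes or inconsistent interval usage."""


_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")
_ICD9_PROC_RE = re.compile(r"^[0-9]{2,4}$")

#: age-group labels in ascending order with (low, high) bounds in years
AGE_GROUPS = (
    ("19-44", 19, 44),
    ("45-64", 45, 64),
    ("65-74", 65, 74),
    ("75+", 75, 200),
)


def normalize_code(raw: str) -> str:
    """Normalize a diagnosis/procedure code: uppercase, strip dots/whitespace.

    >>> normalize_code("e11.5")
    'E115'
    """
    if raw is None:
        raise CodeError("empty code")
    norm = re.sub(r"[.\s]", "", str(raw)).upper()
    if not norm:
        raise CodeError(f"empty code after normalization: {raw!r}")
    if not norm.isalnum():
        raise CodeError(f"non-alphanumeric code: {raw!r}")
    return norm


@dataclass(frozen=True)
class CodeInterval:
    """Inclusive code range ``start``-``end`` within one coding system."""

    start: str
    end: str
    system: str = "icd10_dx"  # or "icd9cm_proc"

    def __post_init__(self):
        object.__setattr__(self, "start", normalize_code(self.start))
        object.__setattr__(self, "end", normalize_code(self.end))
        if self.system not in ("icd10_dx", "icd9cm_proc"):
            raise CodeError(f"unknown coding system {self.system!r}")
        pattern = _ICD10_RE if self.system == "icd10_dx" else _ICD9_PROC_RE
        for code in (self.start, self.end):
            if not pattern.match(code):
                raise CodeError(f"{code!r} not valid for system {self.system}")
        # bare-category prefix relations are legal orderings, e.g. C18.0-C19
        if self.end < self.start and not self.start.startswith(self.end):
            raise CodeError(f"interval start {self.start} after end {self.end}")

    def __contains__(self, code: str) -> bool:
        return code_in_range(code, self)


def code_in_range(code: str, interval: CodeInterval, system: str = "icd10_dx") -> bool:
    """True iff normalized ``code`` lies in the inclusive interval.

    Prefix semantics at both ends: the lower endpoint admits bare-category
    codes (``E11`` is inside ``E11.0-E14.9``) and a bare-category upper
    endpoint covers all its subdivisions (``C34.9`` is inside ``C33-C34.9``,
    ``C19x`` inside ``C18.0-C19``).
    """
    if system != interval.system:
        raise CodeError(
            f"system mismatch: code system {system!r} vs interval {interval.system!r}"
        )
    lower_ok = code >= interval.start or interval.start.startswith(code)
    upper_ok = code <= interval.end or code.startswith(interval.end)
    return lower_ok and upper_ok


#: the cohort-defining malignancy range (principal diagnosis)
CANCER_RANGE = CodeInterval("C00", "C97")


@dataclass
class CodeMap:
    """Named map from condition label to code intervals.

    ``diagnoses`` holds ICD-10 intervals (comorbidities, thyroid disease,
    chemotherapy's Z51.1 session code and the cancer-site ranges);
    ``procedures`` holds ICD-9-CM procedure intervals (chemotherapy,
    radiotherapy). ``sites`` lists the labels treated as mutually exclusive
    cancer sites assigned from the principal diagnosis.
    """

    diagnoses: dict[str, list[CodeInterval]] = field(default_factory=dict)
    procedures: dict[str, list[CodeInterval]] = field(default_factory=dict)
    sites: list[str] = field(default_factory=list)

    def validate(self) -> None:
        """Check site ranges are disjoint and inside the malignancy range."""
        for label in self.sites:
            for iv in self.diagnoses[label]:
                for endpoint in (iv.start, iv.end):
                    if not code_in_range(endpoint, CANCER_RANGE):
                        raise CodeError(
                            f"site {label!r} interval {iv.start}-{iv.end} "
                            "outside C00-C97"
                        )
        for i, a in enumerate(self.sites):
            for b in self.sites[i + 1 :]:
                for iva in self.diagnoses[a]:
                    for ivb in self.diagnoses[b]:
                        if _intervals_overlap(iva, ivb):
                            raise CodeError(
                                f"site ranges overlap: {a!r} and {b!r}"
                            )

    def site_of(self, principal_norm: str) -> str:
        """Cancer-site label for a normalized principal diagnosis.

        Falls back to ``"Other"`` for malignancies outside all named
        site ranges.
        """
        for label in self.sites:
            if any(code_in_range(principal_norm, iv) for iv in self.diagnoses[label]):
                return label
        return "Other"

    def matches_dx(self, label: str, codes_norm: list[str]) -> bool:
        ivs = self.diagnoses.get(label, [])
        return any(code_in_range(c, iv) for c in codes_norm for iv in ivs)

    def matches_proc(self, label: str, codes_norm: list[str]) -> bool:
        ivs = self.procedures.get(label, [])
        return any(
            code_in_range(c, iv, system="icd9cm_proc")
            for c in codes_norm
            for iv in ivs
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def dump(ivs):
            return [
                iv.start if iv.start == iv.end else f"{iv.start}-{iv.end}"
                for iv in ivs
            ]

        return {
            "diagnoses": {k: dump(v) for k, v in self.diagnoses.items()},
            "procedures": {k: dump(v) for k, v in self.procedures.items()},
            "sites": list(self.sites),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodeMap":
        def load(specs, system):
            out = []
            for s in specs:
                parts = s.split("-")
                if len(parts) == 1:
                    out.append(CodeInterval(parts[0], parts[0], system))
                elif len(parts) == 2:
                    out.append(CodeInterval(parts[0], parts[1], system))
                else:
                    raise CodeError(f"bad interval spec {s!r}")
            return out

        cm = cls(
            diagnoses={
                k: load(v, "icd10_dx") for k, v in d.get("diagnoses", {}).items()
            },
            procedures={
                k: load(v, "icd9cm_proc") for k, v in d.get("procedures", {}).items()
            },
            sites=list(d.get("sites", [])),
        )
        cm.validate()
        return cm

    @classmethod
    def from_yaml(cls, path) -> "CodeMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _intervals_overlap(a: CodeInterval, b: CodeInterval) -> bool:
    return (
        code_in_range(a.start, b)
        or code_in_range(a.end, b)
        or code_in_range(b.start, a)
        or code_in_range(b.end, a)
    )


def default_code_map() -> CodeMap:
    """Default condition/site code map.

    DM, HTN, thyroid disease, chemotherapy and radiotherapy ranges follow
    the registry's operational definitions. Site ranges for stomach,
    colorectal, liver and lung likewise; the remaining sites use the
    conventional ICD-10 site categories (these are assumptions and can be
    overridden from a YAML map). Bile duct is restricted to C24 because the
    liver range C22.0-C22.9 already contains intrahepatic bile duct (C22.1)
    and the site partition must stay disjoint.
    """
    dx = {
        "dm": [CodeInterval("E11.0", "E14.9")],
        "htn": [CodeInterval("I10", "I10")],
        "hyperthyroidism": [CodeInterval("E05.0", "E05.9")],
        "hypothyroidism": [
            CodeInterval("E02", "E03.9"),
            CodeInterval("E89.0", "E89.0"),
        ],
        "chemotherapy": [CodeInterval("Z51.1", "Z51.1")],
        # cancer sites (principal diagnosis only)
        "Stomach cancer": [CodeInterval("C16.0", "C16.9")],
        "Colorectal cancer": [CodeInterval("C18.0", "C19")],
        "Liver cancer": [CodeInterval("C22.0", "C22.9")],
        "Lung cancer": [CodeInterval("C33", "C34.9")],
        "Pancreatic cancer": [CodeInterval("C25", "C25")],
        "Bile duct cancer": [CodeInterval("C24", "C24")],
        "Gallbladder cancer": [CodeInterval("C23", "C23")],
        "Small intestine cancer": [CodeInterval("C17", "C17")],
        "Multiple myeloma": [CodeInterval("C90", "C90")],
        "Kidney cancer": [CodeInterval("C64", "C64")],
        "Ureter cancer": [CodeInterval("C66", "C66")],
        "Bladder cancer": [CodeInterval("C67", "C67")],
        "Laryngeal cancer": [CodeInterval("C32", "C32")],
        "Prostate cancer": [CodeInterval("C61", "C61")],
        "Anal cancer": [CodeInterval("C21", "C21")],
        "Esophageal cancer": [CodeInterval("C15", "C15")],
    }
    proc = {
        "chemotherapy": [CodeInterval("99.25", "99.25", "icd9cm_proc")],
        # read as 92.21-92.27 plus the single code 92.29
        "radiotherapy": [
            CodeInterval("92.21", "92.27", "icd9cm_proc"),
            CodeInterval("92.29", "92.29", "icd9cm_proc"),
        ],
    }
    sites = [
        "Stomach cancer",
        "Colorectal cancer",
        "Liver cancer",
        "Lung cancer",
        "Pancreatic cancer",
        "Bile duct cancer",
        "Gallbladder cancer",
        "Small intestine cancer",
        "Multiple myeloma",
        "Kidney cancer",
        "Ureter cancer",
        "Bladder cancer",
        "Laryngeal cancer",
        "Prostate cancer",
        "Anal cancer",
        "Esophageal cancer",
    ]
    cm = CodeMap(diagnoses=dx, procedures=proc, sites=sites)
    cm.validate()
    return cm


@dataclass(frozen=True)
class PhenotypeProfile:
    """Per-episode boolean flags, cancer-site label and demographics."""

    record_id: str
    dm: bool
    htn: bool
    hyperthyroidism: bool
    hypothyroidism: bool
    surgery: bool
    chemotherapy: bool
    radiotherapy: bool
    cancer_site: str
    died: bool
    sex: str
    age_group: str


def age_group_of(age_years: int) -> str:
    for label, lo, hi in AGE_GROUPS:
        if lo <= age_years <= hi:
            return label
    raise ValueError(f"age {age_years} outside the adult cohort range")


def phenotype_record(record, code_map: CodeMap) -> PhenotypeProfile:
    """Phenotype one cohort-filtered discharge record.

    Comorbidity and thyroid flags look at *any* diagnosis position
    (principal or secondary) -- the principal diagnosis is a malignancy by
    cohort definition, so chronic comorbidities can only appear as
    secondary codes. Chemotherapy is accepted from either the 99.25
    procedure or the Z51.1 session diagnosis; the cancer site comes from
    the principal diagnosis alone.
    """
    principal = normalize_code(record.principal_dx)
    if not code_in_range(principal, CANCER_RANGE):
        raise ValueError(
            f"record {record.record_id}: principal diagnosis "
            f"{record.principal_dx!r} outside C00-C97; cohort filter missing?"
        )
    all_dx = [principal] + [normalize_code(c) for c in record.secondary_dx]
    procs = [normalize_code(c) for c in record.procedure_codes]
    return PhenotypeProfile(
        record_id=record.record_id,
        dm=code_map.matches_dx("dm", all_dx),
        htn=code_map.matches_dx("htn", all_dx),
        hyperthyroidism=code_map.matches_dx("hyperthyroidism", all_dx),
        hypothyroidism=code_map.matches_dx("hypothyroidism", all_dx),
        surgery=bool(record.main_surgery_code),
        chemotherapy=(
            code_map.matches_proc("chemotherapy", procs)
            or code_map.matches_dx("chemotherapy", all_dx)
        ),
        radiotherapy=code_map.matches_proc("radiotherapy", procs),
        cancer_site=code_map.site_of(principal),
        died=record.treatment_outcome == "death",
        sex=record.sex,
        age_group=age_group_of(record.age_years),
    )


def phenotype_cohort(cohort, code_map: CodeMap | None = None):
    """Phenotype every record of a cohort into a profiles DataFrame.

    Columns mirror :class:`PhenotypeProfile`; one row per record, input
    order preserved.
    """
    import pandas as pd

    if code_map is None:
        code_map = default_code_map()
    profiles = [phenotype_record(r, code_map) for r in cohort.records]
    return pd.DataFrame([p.__dict__ for p in profiles])
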