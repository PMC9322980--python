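"""Discharge-record table I/O, schema validation and the cohort filter.

One row per discharge episode. The registry provides no person-level
identifier, so every episode is treated as an independent record
throughout the pipeline.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

from .phenotyping import CANCER_RANGE, CodeError, code_in_range, normalize_code

logger = logging.getLogger(__name__)

__all__ = [
    "DischargeRecord",
    "Cohort",
    "SchemaError",
    "RowValidationError",
    "read_cohort",
    "write_cohort",
    "filter_cohort",
    "COLUMNS",
]

COLUMNS = [
    "record_id",
    "sex",
    "age_years",
    "insurance_type",
    "admission_route",
    "treatment_outcome",
    "principal_dx",
    "secondary_dx",
    "procedure_codes",
    "main_surgery_code",
]

SEX_VALUES = {"male", "female"}
INSURANCE_VALUES = {"national_health", "medicaid_1", "medicaid_2", "other"}
ADMISSION_VALUES = {"emergency", "outpatient", "other"}
OUTCOME_VALUES = {"improved", "not_improved", "death", "other"}


class SchemaError(ValueError):
    """Header/column-level problem in a cohort file."""


class RowValidationError(ValueError):
    """One or more rows failed validation; carries (row, message) pairs."""

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{more}")


@dataclass(frozen=True)
class DischargeRecord:
    """A single hospital discharge episode."""

    record_id: str
    sex: str
    age_years: int
    insurance_type: str
    admission_route: str
    treatment_outcome: str
    principal_dx: str
    secondary_dx: tuple[str, ...] = ()
    procedure_codes: tuple[str, ...] = ()
    main_surgery_code: str | None = None

    def validate(self) -> list[str]:
        """Return a list of validation messages (empty when valid)."""
        problems = []
        if not self.record_id:
            problems.append("record_id empty")
        if self.sex not in SEX_VALUES:
            problems.append(f"sex {self.sex!r} not in {sorted(SEX_VALUES)}")
        if not isinstance(self.age_years, int) or self.age_years < 0:
            problems.append(f"age_years {self.age_years!r} not a non-negative integer")
        if self.insurance_type not in INSURANCE_VALUES:
            problems.append(f"insurance_type {self.insurance_type!r} invalid")
        if self.admission_route not in ADMISSION_VALUES:
            problems.append(f"admission_route {self.admission_route!r} invalid")
        if self.treatment_outcome not in OUTCOME_VALUES:
            problems.append(f"treatment_outcome {self.treatment_outcome!r} invalid")
        if not self.principal_dx:
            problems.append("principal_dx empty")
        return problems


@dataclass
class Cohort:
    """Ordered collection of discharge records."""

    records: list[DischargeRecord] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class Dialect:
    """CSV layout knobs: field delimiter and within-cell list separator."""

    delimiter: str = ","
    list_separator: str = ";"


def _parse_row(row: dict, rownum: int, dialect: Dialect):
    errors = []
    age_raw = row.get("age_years", "")
    try:
        age = int(age_raw)
    except (TypeError, ValueError):
        errors.append((rownum, f"unparseable age_years {age_raw!r}"))
        age = -1

    def split_list(cell):
        cell = (cell or "").strip()
        return tuple(c.strip() for c in cell.split(dialect.list_separator) if c.strip())

    rec = DischargeRecord(
        record_id=(row.get("record_id") or "").strip(),
        sex=(row.get("sex") or "").strip(),
        age_years=age,
        insurance_type=(row.get("insurance_type") or "").strip(),
        admission_route=(row.get("admission_route") or "").strip(),
        treatment_outcome=(row.get("treatment_outcome") or "").strip(),
        principal_dx=(row.get("principal_dx") or "").strip(),
        secondary_dx=split_list(row.get("secondary_dx")),
        procedure_codes=split_list(row.get("procedure_codes")),
        main_surgery_code=(row.get("main_surgery_code") or "").strip() or None,
    )
    errors.extend((rownum, msg) for msg in rec.validate())
    return rec, errors


def read_cohort(path, dialect: Dialect | None = None, strict: bool = True) -> Cohort:
    """Read a cohort CSV.

    In strict mode (default) any invalid row aborts the read with a
    :class:`RowValidationError` listing row numbers; with ``strict=False``
    invalid rows are dropped and logged instead — registry analyses should
    never lose rows silently.
    """
    dialect = dialect or Dialect()
    records, errors, seen_ids = [], [], set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected header {COLUMNS}")
        missing = [c for c in COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        for rownum, row in enumerate(reader, start=2):
            rec, errs = _parse_row(row, rownum, dialect)
            if rec.record_id in seen_ids:
                errs.append((rownum, f"duplicate record_id {rec.record_id!r}"))
            if errs:
                errors.extend(errs)
                if not strict:
                    continue
            else:
                seen_ids.add(rec.record_id)
            records.append(rec)
    if errors:
        if strict:
            raise RowValidationError(errors)
        logger.warning("dropped %d invalid row(s) while reading %s", len(errors), path)
        records = [r for r in records if not r.validate()]
    return Cohort(records)


def write_cohort(cohort: Cohort, path, dialect: Dialect | None = None) -> None:
    """Write a cohort CSV that round-trips bit-identically via read_cohort."""
    dialect = dialect or Dialect()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(COLUMNS)
        for r in cohort:
            writer.writerow(
                [
                    r.record_id,
                    r.sex,
                    r.age_years,
                    r.insurance_type,
                    r.admission_route,
                    r.treatment_outcome,
                    r.principal_dx,
                    dialect.list_separator.join(r.secondary_dx),
                    dialect.list_separator.join(r.procedure_codes),
                    r.main_surgery_code or "",
                ]
            )


def filter_cohort(cohort: Cohort, min_age: int = 19) -> Cohort:
    """Apply the cohort definition: adults with a malignant principal dx.

    Keeps records with ``age_years >= min_age`` and a principal diagnosis
    inside C00-C97 (after normalization). Dropped counts are logged by
    reason; filtering is total and idempotent.
    """
    kept, dropped_age, dropped_dx, dropped_bad = [], 0, 0, 0
    for rec in cohort:
        if rec.age_years < min_age:
            dropped_age += 1
            continue
        try:
            principal = normalize_code(rec.principal_dx)
        except CodeError:
            dropped_bad += 1
            continue
        if not code_in_range(principal, CANCER_RANGE):
            dropped_dx += 1
            continue
        kept.append(rec)
    logger.info(
        "cohort filter: kept %d / %d (dropped: %d under age %d, "
        "%d non-malignant principal dx, %d malformed principal dx)",
        len(kept), cohort.n, dropped_age, min_age, dropped_dx, dropped_bad,
    )
    return Cohort(kept)
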