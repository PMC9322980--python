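import pytest
from hypothesis import given
from hypothesis import strategies as st

from comorbid_arm.phenotyping import (
    CodeError,
    CodeInterval,
    age_group_of,
    code_in_range,
    default_code_map,
    normalize_code,
    phenotype_record,
)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("e11.5", "E115"),
        ("I10", "I10"),
        ("C34.9", "C349"),
        (" z51.1 ", "Z511"),
        ("99.25", "9925"),
    ],
)
def test_normalize_code(raw, expected):
    assert normalize_code(raw) == expected


@pytest.mark.parametrize("raw", ["", "  ", "..", "E1/5", None])
def test_normalize_code_rejects_malformed(raw):
    with pytest.raises(CodeError):
        normalize_code(raw)


DM_RANGE = CodeInterval("E11.0", "E14.9")
LUNG_RANGE = CodeInterval("C33", "C34.9")


@pytest.mark.parametrize(
    "code,interval,expected",
    [
        ("E115", DM_RANGE, True),
        ("E101", DM_RANGE, False),  # type 1 DM codes precede the range
        ("E110", DM_RANGE, True),
        ("E149", DM_RANGE, True),
        ("E15", DM_RANGE, False),
        ("E11", DM_RANGE, True),    # bare category inside the range
        ("C33", LUNG_RANGE, True),  # bare-category lower endpoint
        ("C331", LUNG_RANGE, True),
        ("C349", LUNG_RANGE, True),
        ("C35", LUNG_RANGE, False),
        ("C199", CodeInterval("C18.0", "C19"), True),  # bare upper endpoint
        ("C20", CodeInterval("C18.0", "C19"), False),
    ],
)
def test_code_in_range_prefix_semantics(code, interval, expected):
    assert code_in_range(code, interval) is expected


def test_code_in_range_rejects_system_mismatch():
    proc = CodeInterval("92.21", "92.27", "icd9cm_proc")
    with pytest.raises(CodeError, match="system"):
        code_in_range("E115", proc)  # default system is icd10_dx


def test_default_map_site_partition_is_disjoint(code_map):
    code_map.validate()  # raises on overlap / out-of-range
    assert code_map.site_of("C220") == "Liver cancer"
    assert code_map.site_of("C221") == "Liver cancer"  # intrahepatic bile duct
    assert code_map.site_of("C240") == "Bile duct cancer"
    assert code_map.site_of("C164") == "Stomach cancer"
    assert code_map.site_of("C80") == "Other"


@pytest.mark.parametrize(
    "age,group",
    [(19, "19-44"), (44, "19-44"), (45, "45-64"), (64, "45-64"),
     (65, "65-74"), (74, "65-74"), (75, "75+"), (101, "75+")],
)
def test_age_group_cut_points(age, group):
    assert age_group_of(age) == group


def test_phenotype_liver_with_comorbidity_codes(record_factory, code_map):
    rec = record_factory(principal_dx="C22.0", secondary_dx=("E11.9", "I10"))
    prof = phenotype_record(rec, code_map)
    assert prof.cancer_site == "Liver cancer"
    assert prof.dm and prof.htn
    assert not (prof.hyperthyroidism or prof.hypothyroidism)


def test_phenotype_absence_of_codes_means_all_flags_false(record_factory, code_map):
    prof = phenotype_record(record_factory(principal_dx="C16.4"), code_map)
    assert prof.cancer_site == "Stomach cancer"
    assert not any(
        [prof.dm, prof.htn, prof.hyperthyroidism, prof.hypothyroidism,
         prof.surgery, prof.chemotherapy, prof.radiotherapy, prof.died]
    )


@pytest.mark.parametrize(
    "procedures,secondary,chemo,radio",
    [
        (("99.25",), (), True, False),       # chemo via procedure code
        ((), ("Z51.1",), True, False),       # chemo via session diagnosis
        (("92.24",), (), False, True),
        (("92.29",), (), False, True),       # the isolated radiotherapy code
        (("92.28",), (), False, False),      # gap between 92.27 and 92.29
        (("92.21", "99.25"), (), True, True),
    ],
)
def test_treatment_flags(record_factory, code_map, procedures, secondary, chemo, radio):
    rec = record_factory(procedure_codes=procedures, secondary_dx=secondary)
    prof = phenotype_record(rec, code_map)
    assert prof.chemotherapy is chemo
    assert prof.radiotherapy is radio


def test_surgery_and_death_flags(record_factory, code_map):
    rec = record_factory(main_surgery_code="S042", treatment_outcome="death")
    prof = phenotype_record(rec, code_map)
    assert prof.surgery and prof.died


def test_non_malignant_principal_dx_is_a_contract_violation(record_factory, code_map):
    with pytest.raises(ValueError, match="C00-C97"):
        phenotype_record(record_factory(principal_dx="I10"), code_map)


CODE_POOL = ["E11.9", "E14.0", "I10", "E05.0", "E03.9", "E89.0", "J18.9", "N18.5"]


@given(codes=st.lists(st.sampled_from(CODE_POOL), max_size=6), seed=st.integers(0, 99))
def test_phenotype_is_independent_of_diagnosis_order(codes, seed):
    import random

    from conftest import make_record

    code_map = default_code_map()
    shuffled = list(codes)
    random.Random(seed).shuffle(shuffled)
    a = phenotype_record(make_record(secondary_dx=tuple(codes)), code_map)
    b = phenotype_record(make_record(secondary_dx=tuple(shuffled)), code_map)
    assert a == b


@given(
    codes=st.lists(st.sampled_from(CODE_POOL), max_size=5),
    extra=st.sampled_from(CODE_POOL),
)
def test_adding_a_diagnosis_never_clears_a_flag(codes, extra):
    from conftest import make_record

    code_map = default_code_map()
    before = phenotype_record(make_record(secondary_dx=tuple(codes)), code_map)
    after = phenotype_record(
        make_record(secondary_dx=tuple(codes) + (extra,)), code_map
    )
    for flag in ("dm", "htn", "hyperthyroidism", "hypothyroidism"):
        assert getattr(after, flag) >= getattr(before, flag)
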