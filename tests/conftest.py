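import pandas as pd
import pytest
from hypothesis import settings

from comorbid_arm.phenotyping import default_code_map
from comorbid_arm.records import DischargeRecord

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def code_map():
    return default_code_map()


def make_record(**overrides) -> DischargeRecord:
    base = dict(
        record_id="R1",
        sex="female",
        age_years=60,
        insurance_type="national_health",
        admission_route="outpatient",
        treatment_outcome="improved",
        principal_dx="C16.0",
        secondary_dx=(),
        procedure_codes=(),
        main_surgery_code=None,
    )
    base.update(overrides)
    return DischargeRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


def make_profiles(rows) -> pd.DataFrame:
    """Profiles frame from compact tuples:
    (dm, htn, hyper, hypo, site) with neutral demographics."""
    data = []
    for i, (dm, htn, hyper, hypo, site) in enumerate(rows):
        data.append(
            dict(
                record_id=f"P{i}",
                dm=dm, htn=htn,
                hyperthyroidism=hyper, hypothyroidism=hypo,
                surgery=False, chemotherapy=False, radiotherapy=False,
                cancer_site=site, died=False,
                sex="female", age_group="45-64",
            )
        )
    return pd.DataFrame(data)


@pytest.fixture
def profiles_factory():
    return make_profiles
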