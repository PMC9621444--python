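import datetime as dt

import pytest

from hhc_cdss.records_io import AdmissionEpisode, PatientDayRecord
from hhc_cdss.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-patient cohort with elevated prevalence so every stage has positives."""
    spec = CohortSpec(n_patients=600, hhc_prevalence=0.03, seed=11)
    return generate_cohort(spec)


@pytest.fixture
def toy_episodes():
    d = dt.date
    return [
        AdmissionEpisode("E1", d(2019, 1, 1), d(2019, 1, 20), "Cancer",
                         is_psychiatric=True),
        AdmissionEpisode("E2", d(2019, 1, 1), d(2019, 1, 20), "Others", is_demo=True),
        AdmissionEpisode("E3", d(2019, 1, 1), d(2019, 1, 3), "Others"),
        AdmissionEpisode("E4", d(2019, 1, 1), d(2019, 1, 20), "CVA",
                         hhc_label=True, hhc_date=d(2019, 1, 2)),
        AdmissionEpisode("E5", d(2019, 1, 1), d(2019, 1, 11), "Dementia"),
        AdmissionEpisode("E6", d(2019, 1, 1), d(2019, 1, 13), "Others",
                         hhc_label=True, hhc_date=d(2019, 1, 10)),
    ]


@pytest.fixture
def complete_day():
    """A fully-observed, unremarkable patient-day."""
    return PatientDayRecord(
        patient_id="P1", date=dt.date(2019, 3, 1), respiratory_rate=16, spo2=98,
        oxygen_prescription=False, body_temperature=37.0, systolic_bp=120,
        heart_rate=70, cs_eye=4, cs_vocal=5, cs_motion=6, pain=1, bsrs=1,
        nutrition=1, cci_raw=2)
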