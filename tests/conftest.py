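import datetime

import pytest

from cytovax.data import AdverseEventRecord, CohortDataset, Patient, SerumSample
from cytovax.simulate import generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort under the default study conditions."""
    return generate_cohort(seed=17)


def make_patient(pid="P01", vaccinated=True, **kw):
    base = dict(
        patient_id=pid,
        vaccinated=vaccinated,
        vaccine_type="BNT162b2" if vaccinated else "none",
        vax1_date=datetime.date(2021, 4, 1) if vaccinated else None,
        vax2_date=datetime.date(2021, 5, 1) if vaccinated else None,
        ici_start_date=datetime.date(2020, 10, 1),
        sex="male",
        age_years=65,
        ecog=1,
        insurance="general",
        tumor_type="melanoma",
        therapy_class="PD-1/PD-L1 mono",
        survival_days=500.0,
        death_observed=False,
    )
    base.update(kw)
    return Patient(**base)


def make_sample(sid, pid, draw, conc):
    return SerumSample(sample_id=sid, patient_id=pid, draw_date=draw, concentrations=conc)


def make_ae(pid, onset, term="fatigue", grade=1, is_irae=False, hosp=False):
    return AdverseEventRecord(
        patient_id=pid, term=term, grade=grade, onset_date=onset,
        is_irae=is_irae, hospitalization=hosp,
    )


@pytest.fixture
def tiny_cohort():
    """One vaccinated patient with baseline + post samples, one unvaccinated."""
    p1 = make_patient("P01")
    p2 = make_patient("P02", vaccinated=False, vax1_date=None, vax2_date=None)
    d = datetime.date
    samples = [
        make_sample("S1", "P01", d(2021, 3, 1), {"IL-6": 9.0, "CXCL8": 99.0}),
        make_sample("S2", "P01", d(2021, 4, 15), {"IL-6": 99.0, "CXCL8": 999.0}),
    ]
    aes = [make_ae("P01", d(2021, 4, 20))]
    return CohortDataset(
        patients=[p1, p2], samples=samples, adverse_events=aes,
        panel=["IL-6", "CXCL8"],
    ).validate()
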