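import pytest

from trimp.cohort import InjuryRecord, PatientRecord
from trimp.synthetic import SimulationConfig, make_catalog, simulate_cohort


def make_patient(pid="p1", *, age=40, gender="male", gcs=15, sbp=120.0,
                 pulse=75.0, rr=16.0, icu_days=0.0, vent_days=0.0,
                 los_days=3.0, outcome="survived", hospital_id="H1",
                 injuries=(("450203", 3),), ecode="E885.9", mechanism=None,
                 cci=0, dx_codes=None, transfer=False, doa=False, ed_only=False):
    """Hand-built patient record with sensible defaults for unit tests."""
    return PatientRecord(
        patient_id=pid, age=age, gender=gender, gcs=gcs, sbp=sbp, pulse=pulse,
        rr=rr, icu_days=icu_days, vent_days=vent_days, los_days=los_days,
        outcome=outcome, hospital_id=hospital_id,
        injuries=[InjuryRecord(pid, predot, sev) for predot, sev in injuries],
        ecode=ecode, mechanism=mechanism, cci=cci, dx_codes=dx_codes,
        transfer_flag=transfer, dead_on_arrival_flag=doa, ed_only_flag=ed_only)


@pytest.fixture(scope="session")
def catalog():
    return make_catalog(seed=3)


@pytest.fixture(scope="session")
def sim_cohort(catalog):
    """A small simulated cohort shared across tests (read-only)."""
    return simulate_cohort(catalog, SimulationConfig(n_patients=6000, seed=11))
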