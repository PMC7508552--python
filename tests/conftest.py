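import numpy as np
import pandas as pd
import pytest

from shocktraj import PatientRecord, SynthConfig, generate_cohort, label_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded synthetic cohort shared by module tests."""
    cfg = SynthConfig(n_patients=60, seed=11)
    records, truth = generate_cohort(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def small_timelines(small_cohort):
    _, records, _ = small_cohort
    return label_cohort(records)


def make_record(patient_id="t0", weight=70.0, obs=(), fluids=(), vaso=(),
                infection=0.0, abx=None, icu_admit=0.0, died=False,
                end_time=None):
    """Hand-built patient record; obs entries are (time_min, feature, value)."""
    frame = pd.DataFrame(obs, columns=["time", "feature", "value"]) if obs else \
        pd.DataFrame(columns=["time", "feature", "value"])
    return PatientRecord(
        patient_id=patient_id, weight_kg=weight, icu_admit=icu_admit,
        suspected_infection_time=infection, observations=frame,
        fluid_events=np.array(fluids, dtype=float).reshape(-1, 2),
        vasopressor_events=np.array(vaso, dtype=float).reshape(-1, 2),
        antibiotic_order_time=abx, died=died, end_time=end_time)
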