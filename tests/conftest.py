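import numpy as np
import pandas as pd
import pytest

from shpred import io as sio
from shpred import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across tests (seeded)."""
    cfg = syn.CohortConfig(n_patients=20, days_per_patient=30,
                           sh_events_per_patient=1.0, seed=7)
    return syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    segments = []
    for trace in small_cohort.traces:
        segments.extend(sio.preprocess_patient([trace], small_cohort.sh_events))
    return segments


def make_run(values, patient_id="P0", start="2023-01-01"):
    return sio.UniformRun(patient_id=patient_id, start=pd.Timestamp(start),
                          values=np.asarray(values, dtype=float))


def make_trace(times_minutes, glucose, patient_id="P0", start="2023-01-01"):
    t0 = pd.Timestamp(start)
    return sio.GlucoseTrace(
        patient_id=patient_id,
        readings=pd.DataFrame({
            "timestamp": [t0 + pd.Timedelta(minutes=float(m))
                          for m in times_minutes],
            "glucose": np.asarray(glucose, dtype=float),
            "source": "test",
        }))
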