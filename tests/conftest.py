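import numpy as np
import pytest

from washin import PRINTED_PARAMS, DeliverySettings, PatientCovariates
from washin.fitting import WashInRecord
from washin.synthetic import NoiseModel, generate_cohort_records


@pytest.fixture(scope="session")
def params():
    return PRINTED_PARAMS


@pytest.fixture(scope="session")
def noiseless_records():
    """Small zero-noise derivation-style dataset (deterministic)."""
    return generate_cohort_records(
        n=10, noise=NoiseModel(sd=0.0, between_patient_cv=0.0), seed=11)


@pytest.fixture()
def simple_record():
    """Hand-built record: fixed settings, four usable samples."""
    return WashInRecord(
        patient=PatientCovariates(height_cm=170.0, weight_kg=70.0,
                                  age_years=50.0),
        settings=DeliverySettings(fgf=2.0, dial=10.0),
        time_s=np.array([60.0, 120.0, 180.0, 240.0]),
        fa_pct=np.array([1.5, 2.5, 3.2, 3.7]),
        patient_id="p000",
    )
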