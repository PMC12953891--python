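import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ftburden as fb

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def acq():
    return fb.AcquisitionParams()


@pytest.fixture(scope="session")
def lesion_spec():
    return fb.LesionSpec(
        center_vox=(15.5, 15.5, 7.0),
        radius_vox=(6.0, 6.0, 3.0),
        frac_low=0.44,
        frac_mid=0.19,
        frac_high=0.37,
    )


@pytest.fixture(scope="session")
def noiseless_patient(acq, lesion_spec):
    """One noiseless phantom with leakage, shared across modules."""
    return fb.build_patient(
        lesion_spec, "TP", acq, noise_sd=0.0, rng=np.random.default_rng(11)
    )


@pytest.fixture(scope="session")
def noiseless_result(acq, noiseless_patient):
    p = noiseless_patient
    return fb.quantify_patient(
        p.dsc, p.t1_pre, p.t1_post, acq, patient_id=p.patient_id, label=p.truth.label
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    return 2 * np.count_nonzero(a & b) / (a.sum() + b.sum())
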