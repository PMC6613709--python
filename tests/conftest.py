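import numpy as np
import pytest

from gadoflux import DoseProtocol, PhysiologicalConstants, RateParameters
from gadoflux.synthetic_cohort import CohortSpec, generate_cohort, generate_patient


@pytest.fixture(scope="session")
def constants():
    return PhysiologicalConstants()


@pytest.fixture(scope="session")
def dose70():
    return DoseProtocol(body_weight=70.0)


@pytest.fixture(scope="session")
def typical_params():
    """Healthy-population typical parameter values."""
    return RateParameters(k_diff=1.7e-3, k_ph=4.7e-3, k_hp=28e-3, k_hb=38e-3, xi=1.6)


@pytest.fixture(scope="session")
def noisefree_patient(typical_params):
    """One virtual subject observed without measurement noise."""
    spec = CohortSpec(n_patients=1, stage_counts=(1, 0, 0, 0, 0), noise_sd=0.0, seed=3)
    rng = np.random.default_rng(3)
    return generate_patient(typical_params, "F0", spec, rng, patient_id="NF01",
                            body_weight=70.0)


@pytest.fixture(scope="session")
def noisy_patient(typical_params):
    """The same subject with the study-level 0.18 ΔR1 noise."""
    spec = CohortSpec(n_patients=1, stage_counts=(1, 0, 0, 0, 0), seed=5)
    rng = np.random.default_rng(5)
    return generate_patient(typical_params, "F0", spec, rng, patient_id="NY01",
                            body_weight=70.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight virtual subjects, single stage, fixed seed."""
    spec = CohortSpec(n_patients=8, stage_counts=(8, 0, 0, 0, 0), seed=21)
    return generate_cohort(spec)
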