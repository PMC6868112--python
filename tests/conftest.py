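import numpy as np
import pytest

from glucagon_challenge import (
    FixedKinetics,
    NoiseModel,
    ObservationSchedule,
    Protocol,
    SubjectParameters,
    apply_baseline_constraints,
    make_baseline,
    observe,
    simulate_subject,
)


@pytest.fixture(scope="session")
def fixed():
    return FixedKinetics()


@pytest.fixture(scope="session")
def protocol():
    return Protocol()


@pytest.fixture(scope="session")
def avg_subject(fixed):
    """Cohort-average subject with constraint-consistent (b_G, V_ii) and its
    baseline steady state (basal glucose 0.9 g/L, insulin 10 mU/L,
    glucagon 14.3 pmol/L)."""
    params = SubjectParameters()
    baseline = make_baseline(0.9, 10.0, 14.3, params, fixed)
    return apply_baseline_constraints(params, baseline, fixed), baseline


@pytest.fixture(scope="session")
def avg_trajectory(avg_subject, protocol, fixed):
    params, baseline = avg_subject
    return simulate_subject(params, protocol, fixed, baseline)


@pytest.fixture(scope="session")
def noiseless_record(avg_trajectory):
    """The average subject observed on the study schedule with zero noise."""
    zero = NoiseModel(cv_G=0, cv_I=0, cv_E=0, cv_Fhgp=0, cv_Rd=0, seed=0)
    return observe(avg_trajectory, ObservationSchedule(), zero, "AVG", "before")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
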