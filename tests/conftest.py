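import numpy as np
import pytest

from rdspse.data import Participant, RDSSample
from rdspse.model import MeasErrParams
from rdspse.simulate import SimConfig, generate_population, simulate_rds
from rdspse.superpop import SuperpopParams


def make_sample(degrees, recruiters=None, label="test"):
    """RDSSample from a list of degrees; participant i recruited by i-1
    unless a recruiter list is given (None = seed)."""
    parts = []
    for i, dk in enumerate(degrees):
        if recruiters is None:
            rid = None if i == 0 else f"P{i:03d}"
        else:
            rid = recruiters[i]
        parts.append(Participant(
            participant_id=f"P{i + 1:03d}", recruiter_id=rid,
            enrollment_index=i + 1, degree_known=dk,
            coupons_issued=len(degrees),
        ))
    return RDSSample(participants=parts, label=label)


@pytest.fixture(scope="session")
def sim_population():
    cfg = SimConfig(N=500, target_n=150, superpop=SuperpopParams(10, 5), rng_seed=7)
    return generate_population(cfg), cfg


@pytest.fixture(scope="session")
def sim_sample(sim_population):
    pop, cfg = sim_population
    sample, truth = simulate_rds(pop, cfg)
    return sample


@pytest.fixture(scope="session")
def exact_reports_sample():
    """Simulated survey whose reports equal the true visibilities."""
    cfg = SimConfig(N=400, target_n=120, superpop=SuperpopParams(8, 4),
                    meas_err=MeasErrParams(tau=1.0, rho=0.0), rng_seed=21)
    pop = generate_population(cfg)
    sample, truth = simulate_rds(pop, cfg)
    return pop, sample, truth
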