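import numpy as np
import pytest
from hypothesis import settings

from filtergate.synthetic import (
    GroundTruth,
    OFDuty,
    default_design,
    default_ground_truth,
    generate_dataset,
)

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def model(truth):
    return truth.model()


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def noisefree_dataset(truth):
    """Noise-free dataset under the default truth (O-F duty factor active)."""
    return generate_dataset(truth, noise=False, seed=1)


@pytest.fixture(scope="session")
def clean_dataset(truth):
    """Noise-free dataset with a unit O-F duty factor: model predictions exactly."""
    unit = GroundTruth(
        model_name=truth.model_name,
        params=truth.params,
        link=truth.link,
        of_duty=OFDuty(k_OF=0.0),
        kmo=truth.kmo,
    )
    return generate_dataset(unit, noise=False, seed=1)


def random_rate_params(model, rng):
    """Random positive rates/barriers for a model (oracle comparisons)."""
    from filtergate.models import EyringBarrier, RateParameterSet

    base = {e.param: float(10 ** rng.uniform(6, 9)) for e in model.edges}
    eyring = {
        g: EyringBarrier(s=float(rng.uniform(0.05, 0.95)), v_char=float(rng.uniform(20, 150)))
        for g in model.eyring_groups()
    }
    return RateParameterSet(base_rates=base, eyring=eyring)
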