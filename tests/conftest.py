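import numpy as np
import pytest

from stabkin.datamodel import AttributeMap
from stabkin.synthetic import (
    GroundTruth,
    StudyDesign,
    get_fixture,
    printed_model_fixtures,
    simulate_study,
)


@pytest.fixture(scope="session")
def all_fixtures():
    return printed_model_fixtures()


@pytest.fixture(scope="session")
def zero_order_purity_truth():
    """One-step zero-order purity-loss model (lnA=15.7, Ea=86.6 kJ/mol)."""
    return get_fixture("Combi_F2-PM1", "purity")


@pytest.fixture(scope="session")
def two_step_hmwp_truth():
    """Two-step HMWP model with weights 0.67/0.33."""
    return get_fixture("Combi_F1-PM1", "hmwp_increase")


def as_progress_truth(truth):
    """Same kinetics, identity attribute map (raw reaction-progress data)."""
    return GroundTruth(
        name=truth.name,
        attribute="progress",
        model=truth.model,
        amap=AttributeMap.identity(),
    )


@pytest.fixture(scope="session")
def noiseless_zero_order_dataset(zero_order_purity_truth):
    return simulate_study(StudyDesign(noise_sd=0.0), zero_order_purity_truth)


@pytest.fixture(scope="session")
def noisy_zero_order_dataset(zero_order_purity_truth):
    return simulate_study(StudyDesign(noise_sd=0.1, seed=7), zero_order_purity_truth)
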