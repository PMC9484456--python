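import numpy as np
import pytest
from hypothesis import settings

import cortsim as cs

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def example_params() -> cs.ResponseParams:
    """The worked response: B=5, T_on=3, T_max=30, M=25, D=10, T_ret=20, E=6."""
    return cs.ResponseParams(
        baseline=5.0,
        onset_delay=3.0,
        time_to_max=30.0,
        max_value=25.0,
        plateau_duration=10.0,
        return_duration=20.0,
        end_value=6.0,
    )


@pytest.fixture(scope="session")
def default_pop() -> cs.PopulationSpec:
    return cs.default_population()


@pytest.fixture(scope="session")
def small_dataset(default_pop) -> cs.ObservedDataset:
    """40 individuals, 3 events, fixed 1/15/30 design with assay error."""
    cohort = cs.sample_population(default_pop, 40, seed=1234)
    return cs.simulate_dataset(
        cohort,
        expr=cs.ExpressionSpec(fidelity=0.6),
        design=cs.SamplingDesign(kind="fixed", fixed_times=(1, 15, 30)),
        assay=cs.AssayModel(error_sd=1.0),
        n_events=3,
        seed=5678,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
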