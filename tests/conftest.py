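import numpy as np
import pandas as pd
import pytest

from paridmorph import data_io, morphostats
from paridmorph.synthetic_data import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A 6-species x 5-individual synthetic study shared across tests."""
    return generate_study(SimulationConfig(n_species=6, n_per_species=5, seed=11))


@pytest.fixture(scope="session")
def small_study_tables(small_study):
    frame = data_io.measurements_frame(small_study.measurements)
    log_traits = morphostats.log_transform(frame[list(data_io.MEASUREMENT_TRAITS)])
    return frame, log_traits


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_shapes(rng, n, k=8, spread=0.05):
    """Random perturbations of one base shape: a plausible GPA input."""
    base = rng.normal(0.0, 1.0, (k, 2))
    return [base + rng.normal(0.0, spread, (k, 2)) for _ in range(n)]
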