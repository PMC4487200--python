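import numpy as np
import pandas as pd
import pytest

from sscexpr import simulate


@pytest.fixture(scope="session")
def sim_cfg():
    return simulate.SimulationConfig(seed=11, n_genes=600, n_signature_genes=60)


@pytest.fixture(scope="session")
def reference_cohort(sim_cfg):
    expr, labels, truth = simulate.generate_reference_cohort(sim_cfg)
    return expr, labels, truth


@pytest.fixture(scope="session")
def trial_cohort(sim_cfg):
    return simulate.generate_trial_cohort(sim_cfg)


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(5)
    m = pd.DataFrame(
        rng.normal(size=(20, 6)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(6)],
    )
    return m
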