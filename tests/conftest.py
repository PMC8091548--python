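import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cernanet.io import ExpressionMatrix
from cernanet.simulate import SimulationConfig, generate_annotation, simulate_study

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_counts(values, features=None, samples=None, layer="counts"):
    arr = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=features, columns=samples), layer=layer)


def make_design(samples, groups):
    return pd.DataFrame({"sample": samples, "group": groups})


@pytest.fixture(scope="session")
def default_study():
    """One default-size simulated study shared across tests (seed 11)."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_annotation():
    cfg = SimulationConfig(
        seed=7, n_mrna=50, n_lncrna=30, n_mirna=10, n_triplets=5, shared_mirnas_per_pair=3
    )
    return cfg, generate_annotation(cfg)
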