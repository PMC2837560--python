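import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sigrev import SimulationConfig, simulate_biopsy_matrix, simulate_treatment_matrix

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def strong_config():
    """Small two-group design with a clearly recoverable planted signature."""
    return SimulationConfig(
        n_probes=300,
        group_sizes={"normal": 6, "adenoma": 8},
        n_signature=10,
        n_reversed=7,
        effect_size=2.0,
        noise_sd=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def strong_biopsy(strong_config):
    return simulate_biopsy_matrix(strong_config)


@pytest.fixture(scope="session")
def strong_treatment(strong_config, strong_biopsy):
    _, _, truth = strong_biopsy
    return simulate_treatment_matrix(strong_config, truth)


@pytest.fixture
def toy_matrix():
    """Two probes, two groups of three samples, deterministic values."""
    m = pd.DataFrame(
        {
            "a1": [1.0, 5.0], "a2": [2.0, 5.5], "a3": [3.0, 4.5],
            "b1": [3.0, 5.2], "b2": [4.0, 4.8], "b3": [5.0, 5.0],
        },
        index=pd.Index(["p1", "p2"], name="probe_id"),
    )
    ann = pd.Series(
        {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"},
        name="group",
    )
    return m, ann


def random_two_class(rng, n_probes=20, n_a=4, n_b=5):
    """Unstructured random matrix with a two-class annotation."""
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    m = pd.DataFrame(
        rng.normal(size=(n_probes, n_a + n_b)),
        index=pd.Index([f"p{i}" for i in range(n_probes)], name="probe_id"),
        columns=cols,
    )
    ann = pd.Series({c: ("A" if c.startswith("a") else "B") for c in cols}, name="group")
    return m, ann
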