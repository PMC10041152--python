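import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated experiment with two planted effect genes."""
    import phycofit as pf

    config = pf.SimulationConfig(
        n_genes=60,
        read_depth=300_000,
        seed=42,
        effect_table={
            ("SYN01", "Rp+V"): 0.0,
            ("SYN02", "Rp+V+M"): 1.8,
        },
    )
    library = pf.simulate_library(config)
    exp = pf.simulate_experiment(config, library)
    return config, exp


@pytest.fixture(scope="session")
def small_result(small_experiment):
    import phycofit as pf

    config, exp = small_experiment
    result, truth = pf.run_simulated(config, exp=exp, seed=42)
    return result, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
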