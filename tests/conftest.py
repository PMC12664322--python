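import numpy as np
import pandas as pd
import pytest

from budwormflight.simulate import (
    GeneratorConfig,
    generate_females,
    simulate_costs,
    simulate_flight,
)


@pytest.fixture(scope="session")
def females():
    """A mid-size study-shaped trait/environment table (fixed seed)."""
    return generate_females(GeneratorConfig(n_per_treatment=50), seed=42)


@pytest.fixture(scope="session")
def study():
    """Full simulated study (flight + coherent costs), fixed seed."""
    cfg = GeneratorConfig(n_per_treatment=50, mode="coherent")
    fem = generate_females(cfg, seed=7)
    fl = simulate_flight(fem, cfg, seed=8)
    return simulate_costs(fl, cfg, seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
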