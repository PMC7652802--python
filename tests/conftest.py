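"""Shared fixtures: model configurations and small simulated datasets."""

import numpy as np
import pytest

import mdzpopkit as mk
from mdzpopkit.config import design_preset


@pytest.fixture(scope="session")
def model():
    """(pop, re, effects) of the shipped interaction configuration."""
    return mk.load_population_config("table3_interaction.yaml")


@pytest.fixture(scope="session")
def pop(model):
    return model[0]


@pytest.fixture(scope="session")
def re_spec(model):
    return model[1]


@pytest.fixture(scope="session")
def effects(model):
    return model[2]


@pytest.fixture(scope="session")
def re_zero(re_spec):
    return re_spec.zero()


@pytest.fixture(scope="session")
def small_design():
    """Six constitutive subjects, oral + iv occasions, rich sampling."""
    return design_preset("recovery_constitutive", 6)


@pytest.fixture(scope="session")
def small_dataset(small_design, model):
    pop, re, effects = model
    return mk.simulate_dataset(small_design, pop, re, effects, rng_seed=42)


@pytest.fixture(scope="session")
def noiseless_dataset(small_design, model):
    """Same design simulated with zero variability and zero residual error."""
    import dataclasses

    pop, re, effects = model
    pop0 = dataclasses.replace(
        pop, err_early_mdz=1e-4, err_late_mdz=1e-4,
        err_early_ohmdz=1e-4, err_late_ohmdz=1e-4,
    )
    return pop0, mk.simulate_dataset(small_design, pop0, re.zero(), effects, rng_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
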