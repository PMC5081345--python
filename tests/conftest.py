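"""Shared fixtures.  Expensive simulations are session-scoped so the
headline computations (RMP operating points, preset firing, tail-current
activation, population recovery) run once for the whole suite."""

import numpy as np
import pytest

from fusiform import workflows
from fusiform.population import (PopulationConfig, sample_population,
                                 recover_conductances)


@pytest.fixture(scope="session")
def rmp_table():
    """Sodium-zeroed resting potentials at the four reference points."""
    return workflows.rmp_endpoints()


@pytest.fixture(scope="session")
def preset_rates():
    """Spontaneous rates (Hz) of the active/quiet Kir presets."""
    return workflows.preset_firing_rates()


@pytest.fixture(scope="session")
def tail_fit():
    """(step V, activation, BoltzmannFit) from the simulated tail protocol."""
    return workflows.ih_activation_from_tails()


@pytest.fixture(scope="session")
def default_population():
    """Seeded 12-neuron population with the default class statistics."""
    cfg = PopulationConfig(n_per_class=6, seed=1)
    return sample_population(cfg)


@pytest.fixture(scope="session")
def recovery_table(default_population):
    """Noise-free conductance estimates for the default population."""
    return recover_conductances(default_population)


@pytest.fixture(scope="session")
def equalization():
    """Input-resistance change on HCN removal, both presets."""
    return workflows.gh_removal_effect()
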