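import warnings

import numpy as np
import pytest

from errorshift import (
    Calibration,
    RateScheme,
    build_simulation_tree,
    draw_branch_rates,
    simulate_alignment,
)

warnings.filterwarnings("ignore", message=".*ArviZ is undergoing a major refactor.*")


@pytest.fixture(scope="session")
def sim_tree():
    return build_simulation_tree()


@pytest.fixture(scope="session")
def full_calibrations(sim_tree):
    cals = {"root": Calibration("root", 180.0, 220.0)}
    for tag in ("I", "II", "III", "IV", "V", "VI"):
        age = sim_tree.ages[sim_tree.node(tag)]
        cals[tag] = Calibration.symmetric(tag, age, 0.10 * age)
    return cals


@pytest.fixture(scope="session")
def small_mixed_alignment(sim_tree):
    """One 2-kb mixed-rates replicate, small enough for fast MCMC tests."""
    rng = np.random.default_rng(42)
    rates = draw_branch_rates(sim_tree, RateScheme.mixed(sim_tree), rng)
    return simulate_alignment(sim_tree, rates, length=2_000, seed=rng), rates
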