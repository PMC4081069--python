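"""Shared fixtures: scenarios and small simulated ensembles (session-scoped,
generated programmatically; nothing is read from disk)."""

import numpy as np
import pytest

from forcemelt.constructs import load_scenario
from forcemelt.simulate import simulate_molecule


@pytest.fixture(scope="session")
def five_prime_high():
    return load_scenario("FIVE_PRIME_AT", "HIGH_1M")


@pytest.fixture(scope="session")
def three_five_high():
    return load_scenario("THREE_FIVE_PRIME_AT", "HIGH_1M")


@pytest.fixture(scope="session")
def three_five_low():
    return load_scenario("THREE_FIVE_PRIME_AT", "LOW_5MM")


@pytest.fixture(scope="session")
def atgc_high():
    return load_scenario("ATGC", "HIGH_1M")


@pytest.fixture(scope="session")
def five_prime_cycles(five_prime_high):
    """Six 5'AT pull-relax cycles with ground truth, fixed seed."""
    return simulate_molecule(five_prime_high, 6, seed=1101)


@pytest.fixture(scope="session")
def three_five_eq_cycles(three_five_high):
    """Five reversible 3'5'AT cycles (equilibrium pathway only)."""
    return simulate_molecule(three_five_high, 5, seed=1201,
                             hysteretic_pathway_probability=0.0)


@pytest.fixture(scope="session")
def atgc_cycles(atgc_high):
    """Five ATGC cycles with bistable hopping through both transitions."""
    return simulate_molecule(atgc_high, 5, seed=1301)
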