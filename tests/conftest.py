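import numpy as np
import pytest

import fohi


@pytest.fixture(scope="session")
def fukuoka():
    return fohi.fukuoka_default_hierarchy()


@pytest.fixture(scope="session")
def raw_table(fukuoka):
    """Study-shaped synthetic raw table: 60 units, 34 indicators, seed 7."""
    profile = fohi.default_profile(fukuoka, n_units=60, seed=7)
    return fohi.generate_indicator_table(fukuoka, profile)


@pytest.fixture(scope="session")
def standardized(raw_table):
    return fohi.standardize_table(raw_table)


@pytest.fixture(scope="session")
def weight_tree(fukuoka):
    """Weight tree from simulated 23-expert panels at a fixed seed."""
    from fohi.io import simulate_default_votes

    votes = simulate_default_votes(fukuoka, n_experts=23, seed=11)
    return fohi.derive_weight_tree(votes, fukuoka)


@pytest.fixture(scope="session")
def score_hierarchy(standardized, weight_tree, fukuoka):
    return fohi.aggregate_hierarchy(standardized.scores, weight_tree, fukuoka)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
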