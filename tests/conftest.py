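import numpy as np
import pytest

from lichenbgc import simdata


@pytest.fixture(scope="session")
def community_sim():
    """One default-community metagenome simulation shared by unit tests."""
    contigs, coverage, taxonomy, truth = simdata.simulate_metagenome(
        simdata.default_community(), seed=11
    )
    return contigs, coverage, taxonomy, truth


@pytest.fixture(scope="session")
def panel_sim():
    """One archetype-panel simulation shared by networking unit tests."""
    archetypes = simdata.random_archetypes(8, seed=3)
    clade_map = {f"G{i:02d}": "cladeA" for i in range(5)}
    params = simdata.EvolutionParams(seed=42)
    clusters, truth = simdata.simulate_bgc_panel(archetypes, clade_map, params)
    return clusters, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
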