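import numpy as np
import pytest

import g4boost as g


@pytest.fixture(scope="session")
def energy_table():
    """One shared lazy energy table (ViennaRNA-backed when available)."""
    return g.build_energy_table()


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic genome + truth + track shared across tests."""
    genome, truth = g.generate_genome(n_pqs=200, length=45_000, seed=101)
    track = g.generate_mm_track(truth, genome, noise_sd=3.0, seed=102)
    return genome, truth, track


@pytest.fixture(scope="session")
def small_dataset(small_world, energy_table):
    genome, truth, track = small_world
    return g.make_dataset(truth, genome, track, energy_table=energy_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
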