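import numpy as np
import pytest

import welltrace as wt


@pytest.fixture(scope="session")
def small_layout():
    """Two-subarray 14x28 plate: 14 x, 14 y, 2 z oligos."""
    return wt.build_layout(14, 28, 14, 14, seed=0)


@pytest.fixture(scope="session")
def single_tile_layout():
    return wt.build_layout(14, 14, 14, 14, seed=0)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Small noiseless experiment: every bead recovered, no ambient noise."""
    cfg = wt.SimConfig(
        seed=11,
        n_rows=14,
        n_cols=28,
        beads_per_well=2,
        bead_recovery_prob=1.0,
        ambient_index_rate=0.0,
        misprint_rate=0.0,
        cross_contamination_rate=0.0,
        transcripts_per_cell_mean=300.0,
        n_genes_per_species=80,
    )
    return wt.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Small experiment at the generator's default noise levels."""
    cfg = wt.SimConfig(seed=23, n_rows=28, n_cols=28)
    return wt.simulate_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
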