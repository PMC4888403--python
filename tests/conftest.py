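"""Shared fixtures: desk-scale grids and simulated cells.

Expensive objects (genome-proportioned grids, fitted HMMs) are
session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest

import scploidy as sp


@pytest.fixture(scope="session")
def grch_grid() -> sp.BinGrid:
    """GRCh37-proportioned grid at 1/5 scale: ~620 one-Mb bins, 24 chromosomes."""
    return sp.simulate_grch37_grid(seed=1)


@pytest.fixture(scope="session")
def sim_config() -> sp.SimulationConfig:
    return sp.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def small_grid() -> sp.BinGrid:
    """Cheap 8-chromosome grid (~160 bins) for metric-level tests."""
    lengths = [30_000_000, 25_000_000, 22_000_000, 20_000_000,
               18_000_000, 16_000_000, 15_000_000, 14_000_000]
    return sp.simulate_bin_grid(8, lengths, 1_000_000, seed=11)


@pytest.fixture(scope="session")
def euploid_cell(grch_grid, sim_config) -> sp.BinnedCell:
    return sp.simulate_cell(grch_grid, sp.KaryotypeSpec.euploid("XX"), sim_config, 777,
                            cell_id="euploid_xx")


@pytest.fixture(scope="session")
def euploid_fit(grch_grid, euploid_cell) -> sp.CopyNumberHMMResults:
    corrected = sp.gc_correct(euploid_cell, grch_grid)
    return sp.fit_copy_number_hmm(corrected.observable(), grch_grid)
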