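"""Shared fixtures: tiny deterministic synthetic datasets and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from scmethyl import data_io, synthetic_data as sd


@pytest.fixture(scope="session")
def micro_sim():
    """2 × 20 kb chromosomes, 3 cells, generic correlation structure."""
    return sd.simulate(sd.SimConfig(
        n_chroms=2, chrom_length=20_000, n_cells=3, cpg_density=0.02,
        base_logit=0.0, gp_sigma=1.5, gp_length_scale=800.0,
        cross_cell_corr=0.6, coverage=0.3, seed=11))


@pytest.fixture(scope="session")
def micro_dataset(micro_sim):
    return data_io.build_dataset(micro_sim.genome, micro_sim.profiles,
                                 sites=micro_sim.cpg_sites, L_win=101, K=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def toy_profile():
    """One cell with a handful of observed sites on two chromosomes."""
    prof = data_io.MethylationProfile(cell_id="cellA")
    prof.positions["1"] = np.array([10, 50, 90, 110, 200], dtype=np.int64)
    prof.states["1"] = np.array([1, 0, 1, 0, 1], dtype=np.uint8)
    prof.positions["2"] = np.array([30], dtype=np.int64)
    prof.states["2"] = np.array([0], dtype=np.uint8)
    return prof
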