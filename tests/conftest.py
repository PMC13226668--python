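"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

from isletdeck.io_cohort import CountsMatrix
from isletdeck.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Two multiplexed donors, small gene panel; fast enough for many tests."""
    return SimulationConfig(
        seed=11,
        n_donors=(1, 0, 1),
        cells_per_donor=250,
        n_genes=400,
        n_empty_droplets=400,
        n_variants=60,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def mid_cohort():
    """Six donors (2 per state), used for composition and QC checks."""
    cfg = SimulationConfig(
        seed=13,
        n_donors=(2, 2, 2),
        cells_per_donor=200,
        n_genes=400,
        n_empty_droplets=300,
        n_variants=30,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def tiny_counts() -> CountsMatrix:
    mat = sp.csc_matrix(np.array([[3, 0], [0, 1]]))
    return CountsMatrix(mat, ["g1", "g2"], ["c1", "c2"], library_id="T")


def make_counts(arr, genes=None, barcodes=None, lib="L"):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    barcodes = barcodes or [f"c{i}" for i in range(arr.shape[1])]
    return CountsMatrix(sp.csc_matrix(arr), genes, barcodes, library_id=lib)
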