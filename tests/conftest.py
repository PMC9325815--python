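import numpy as np
import pandas as pd
import pytest

from selresp.markers import KinshipMatrix, MarkerMatrix, vanraden_kinship
from selresp.simdata import SimConfig, simulate_met, simulate_program


def make_markers(n_entries=30, n_markers=200, seed=0, prefix="E"):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, n_markers)
    dos = rng.binomial(2, p, size=(n_entries, n_markers)).astype(float)
    ids = [f"{prefix}{i:03d}" for i in range(n_entries)]
    return MarkerMatrix(ids, dos, [f"M{j:04d}" for j in range(n_markers)])


@pytest.fixture(scope="session")
def small_kinship() -> KinshipMatrix:
    return vanraden_kinship(make_markers(30, 300, seed=4))


@pytest.fixture(scope="session")
def small_met():
    """60 entries, 2 locations, 3 years, both testers; moderate signal."""
    cfg = SimConfig(n_entries_per_cycle=(60, 18, 6), n_years=3, n_locations=2,
                    n_trials_per_location=1, n_blocks_per_rep=4, n_markers=400,
                    sigma2_g=2.0, sigma2_gy=1.4, seed=11)
    return simulate_met(cfg)


@pytest.fixture(scope="session")
def small_program():
    cfg = SimConfig(n_entries_per_cycle=(60, 20, 6), n_cycles=2, n_locations=2,
                    n_trials_per_location=1, n_blocks_per_rep=4, n_markers=300,
                    n_checks=2, seed=5)
    return simulate_program(cfg)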