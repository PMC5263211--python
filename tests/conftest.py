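import numpy as np
import pandas as pd
import pytest
from scipy.linalg import hadamard

from gasel import SimulationConfig, simulate_genotypes, simulate_program, simulate_true_values
from gasel.genomics import MarkerMatrix


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_lines_per_year=60,
        n_years=5,
        n_families=8,
        n_markers=200,
        n_qtl=60,
        pyt_rows=10,
        pyt_cols=9,
        check_reps=10,
        carry_fraction=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_program(small_config):
    return simulate_program(small_config)


@pytest.fixture(scope="session")
def family_panel():
    """150 lines in 8 families plus truth, for kinship-based tests."""
    cfg = SimulationConfig(
        n_lines_per_year=150, n_years=1, n_families=8, n_markers=180,
        n_qtl=60, pyt_rows=12, pyt_cols=16, check_reps=12, seed=5,
    )
    rng = np.random.default_rng(5)
    ids = [f"L{i:03d}" for i in range(150)] + ["CHK01", "CHK02", "CHK03"]
    fams = [i % 8 for i in range(150)] + [8, 9, 10]
    mm = simulate_genotypes(cfg, line_ids=ids, families=fams, rng=rng)
    truth = simulate_true_values(mm, cfg, rng=rng)
    return cfg, mm, truth


@pytest.fixture
def hadamard_markers():
    """16 lines x 15 mutually orthogonal, mean-zero +-1 markers (no LD)."""
    H = hadamard(16).astype(float)
    codes = H[:, 1:]  # drop the constant column
    ids = [f"H{i:02d}" for i in range(16)]
    mids = [f"M{j:02d}" for j in range(15)]
    return MarkerMatrix(ids, mids, codes)
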