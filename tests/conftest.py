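import numpy as np
import pandas as pd
import pytest

import admixscan as ax
from admixscan.config import DEFAULT_BETA_A, DEFAULT_BETA_B


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated cohort shared by read-only tests."""
    cfg = ax.SimConfig(n_individuals=60, n_markers=120, n_chromosomes=4, seed=7)
    return ax.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_cohort():
    """200 individuals with fixed true African ancestry 0.84 on a 1,000-marker panel."""
    cfg = ax.SimConfig(n_individuals=200, n_markers=1000, n_chromosomes=22, seed=42)
    rng = np.random.default_rng(np.random.SeedSequence(42).spawn(3)[1])
    panel = ax.simulate_marker_panel(cfg)
    M = 0.16  # European proportion; African = 0.84
    states = np.vstack(
        [ax.simulate_ancestry_tracts(M, cfg.lambda_gen, panel, rng) for _ in range(200)]
    )
    geno = ax.simulate_genotypes(states, panel, cfg.missing_rate, rng)
    return panel, states, geno, M


@pytest.fixture(scope="session")
def recovery_estimates(recovery_cohort):
    """Global-ancestry grid MLEs for the fixed-0.84 cohort (the expensive step)."""
    panel, _states, geno, _M = recovery_cohort
    return ax.estimate_global_ancestry(geno, panel)


@pytest.fixture(scope="session")
def calibrated_beta():
    return ax.calibrate_ancestry_beta()


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def default_beta():
    return DEFAULT_BETA_A, DEFAULT_BETA_B
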