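import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from pcovr_gxe import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small fully-observed cohort with planted main + interaction
    effects, shared across read-only tests."""
    cfg = SimulationConfig(
        n_subjects=400,
        n_snps=40,
        block_sizes=[12, 10, 10, 8],
        effect_intercept_g=0.25,
        effect_intercept_e=0.15,
        effect_intercept_gxe=0.10,
        missing_genotype_rate=0.0,
        seed=123,
    )
    genotypes, table, truth = simulate_cohort(cfg)
    return cfg, genotypes, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
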