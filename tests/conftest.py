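import numpy as np
import pytest

from wgva.simulate import CausalSpec, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact 5-breed cohort with trios and an implanted causal variant."""
    cfg = SimulationConfig(
        seed=42, n_variants=600, n_breeds=5, breed_sizes=(5, 3, 2, 6, 6),
        case_breeds=(0, 1, 2), n_trios=2, n_chromosomes=3,
        causal=CausalSpec(flank_variants=10),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """No missingness, no genotype errors, no causal variant, no LD."""
    cfg = SimulationConfig(
        seed=7, n_variants=400, n_breeds=4, breed_sizes=(6, 5, 5, 4),
        case_breeds=(0,), n_trios=2, n_chromosomes=2, missing_rate=0.0,
        genotype_error_rate=0.0, causal=None, ld_rho=0.0,
    )
    return simulate_cohort(cfg)
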