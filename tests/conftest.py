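import numpy as np
import pytest

from hdlburden import (
    SimulationDesign,
    apply_burden_cascade,
    default_rate_table,
    run_burden,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def rate_table():
    return default_rate_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded cohort shared by read-only tests."""
    design = SimulationDesign(
        seed=42, n_genes=40, n_participants=60, total_expected_damaging=120.0
    )
    return simulate_cohort(design)


@pytest.fixture(scope="session")
def null_burden_run():
    """Full null pipeline at study scale: 204 participants, 200 genes."""
    design = SimulationDesign(seed=7)
    cohort = simulate_cohort(design)
    kept, tally = apply_burden_cascade(cohort.variants, 1e-3)
    results = run_burden(kept, cohort.genes)
    return cohort, kept, tally, results


@pytest.fixture
def rng():
    return np.random.default_rng(0)
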