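import numpy as np
import pytest

from dispred import data_io, sim


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated admixed cohort shared across tests (read-only)."""
    cfg = sim.SimulationConfig(
        n_individuals=300,
        n_snps=60,
        n_populations=3,
        n_causal=8,
        missing_rate=0.05,
        seed=7,
    )
    return sim.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    """The same cohort after QC and imputation."""
    cohort = data_io.filter_by_missingness(small_sim.cohort)
    return data_io.impute_missing(cohort)


@pytest.fixture()
def toy_cohort():
    """Hand-built 4x3 cohort with one missing entry."""
    x = np.array(
        [
            [0.0, 2.0, 1.0],
            [1.0, np.nan, 0.0],
            [2.0, 0.0, 1.0],
            [0.0, 2.0, 2.0],
        ]
    )
    return data_io.Cohort(
        ids=["a", "b", "c", "d"],
        x=x,
        y=np.array([0, 1, 0, 1]),
    )
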