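import numpy as np
import pytest

from zzformer import SimulationConfig, SurvivalCohort, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> SurvivalCohort:
    """Hand-built 6-sample, 4-gene cohort with mixed censoring."""
    rng = np.random.default_rng(7)
    return SurvivalCohort(
        sample_ids=[f"P{i}" for i in range(6)],
        genes=["TP53", "SPP1", "CXCL9", "MMP7"],
        X=rng.standard_normal((6, 4)),
        time=np.array([100.0, 250.0, 80.0, 400.0, 320.0, 150.0]),
        event=np.array([1, 0, 1, 1, 0, 1]),
    )


@pytest.fixture(scope="session")
def sim_small():
    """Small simulated cohort with planted linear signal (fast to fit)."""
    cfg = SimulationConfig(n_samples=160, n_genes=64, signal_genes=8,
                           beta_magnitude=1.0, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sim_fixture():
    """The reference linear-signal simulation used across recovery tests."""
    return simulate_cohort(SimulationConfig(seed=1))
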