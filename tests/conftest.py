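import numpy as np
import pytest

from fhnloop import (
    CouplingConfig,
    FHNParams,
    SolverConfig,
    simulate_hybrid,
)

# The parameter set of the two-unit loop: unit 1 is the electronic
# generator, unit 2 the biological-oscillator surrogate.
UNIT1 = FHNParams(epsilon=0.18, I=0.19, alpha=0.5, beta=2.0)
UNIT2 = FHNParams(epsilon=0.19, I=0.18, alpha=0.5, beta=2.0)
LOOP = CouplingConfig(k=0.0223, d=0.087, forward_on=True, feedback_on=True)


@pytest.fixture(scope="session")
def unit1() -> FHNParams:
    return UNIT1


@pytest.fixture(scope="session")
def unit2() -> FHNParams:
    return UNIT2


@pytest.fixture(scope="session")
def loop() -> CouplingConfig:
    return LOOP


@pytest.fixture(scope="session")
def closed_loop_traj():
    """One settled closed-loop run, shared by metric and acceptance tests."""
    cfg = SolverConfig(horizon=500.0, sample_dt=0.01)
    return simulate_hybrid(UNIT1, UNIT2, LOOP, cfg=cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
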