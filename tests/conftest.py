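import numpy as np
import pytest

import riemannfc as rf


def random_spd(rng: np.random.Generator, k: int, dof: int | None = None
               ) -> np.ndarray:
    """Random SPD matrix from a Wishart-style draw (well-conditioned)."""
    dof = dof or 3 * k
    G = rng.standard_normal((dof, k))
    S = G.T @ G / dof
    return S + 0.1 * np.eye(k)


@pytest.fixture(scope="session")
def planted_result() -> rf.SimulationResult:
    """Reference planted-effect cohort: k=20, T=300, 60+60, 5 edges at 0.3."""
    return rf.simulate_cohort(rf.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def planted_matrices(planted_result) -> list[rf.ConnectivityMatrix]:
    return [rf.fc_from_timeseries(s) for s in planted_result.series]


@pytest.fixture(scope="session")
def null_result() -> rf.SimulationResult:
    """Same conditions with effect = 0 (label-exchangeable groups)."""
    return rf.simulate_cohort(rf.SimulationConfig(effect=0.0, seed=1))


@pytest.fixture(scope="session")
def null_matrices(null_result) -> list[rf.ConnectivityMatrix]:
    return [rf.fc_from_timeseries(s) for s in null_result.series]


@pytest.fixture(scope="session")
def small_cohort() -> tuple[list[rf.ConnectivityMatrix], np.ndarray]:
    """20 subjects, k=15: just enough structure for model-level tests."""
    res = rf.simulate_cohort(rf.SimulationConfig(
        n_per_group=10, k=15, T=200, planted_edges=((0, 1), (2, 3)), seed=11))
    mats = [rf.fc_from_timeseries(s) for s in res.series]
    return mats, res.cohort.indicator()
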