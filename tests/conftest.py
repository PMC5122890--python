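import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import moeanet as mn

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def payoff_matrix():
    return mn.make_payoff_matrix(1.2)


@pytest.fixture(scope="session")
def small_net():
    """ER network, 20 nodes, mean degree ~4, weights U[1,3]."""
    return mn.gen_er(20, 4, seed=0)


@pytest.fixture(scope="session")
def small_trace(small_net):
    return mn.simulate(small_net, mn.SimulationConfig(rounds=32, seed=1))


@pytest.fixture(scope="session")
def small_system(small_trace, payoff_matrix):
    return mn.build_local_system(small_trace, 0, payoff_matrix)


@pytest.fixture(scope="session")
def fast_moea():
    return mn.MOEAConfig(pop_size=30, generations=25, seed=7)


def brute_force_fronts(F):
    """O(n^2) pairwise-dominance front peeling, the sorting oracle."""
    F = np.asarray(F, dtype=float)
    n = len(F)
    dom = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            dom[i, j] = (
                F[i, 0] <= F[j, 0] and F[i, 1] <= F[j, 1]
                and (F[i, 0] < F[j, 0] or F[i, 1] < F[j, 1])
            )
    fronts = []
    remaining = set(range(n))
    while remaining:
        front = sorted(j for j in remaining if not any(dom[i, j] for i in remaining))
        fronts.append(front)
        remaining -= set(front)
    return fronts
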