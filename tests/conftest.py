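import numpy as np
import pytest

from colonyalloc import ChoiceSpec, make_scenario


@pytest.fixture
def sample_execution_scenario():
    """The worked sample execution: demands (2,4,1,3), 12 workers, one
    worker each initially on tasks 2 and 4."""
    return make_scenario((2, 4, 1, 3), 12, (0, 1, 0, 1), label="sample-execution")


@pytest.fixture
def toy_two_tasks():
    """d=(1,1), |A|=2, all idle — the hand-solvable two-state chain."""
    return make_scenario((1, 1), 2, "all-idle", label="toy")


def random_tiny_scenario(rng: np.random.Generator, max_workers=6, max_tasks=3):
    """A random instance small enough for exact chain analysis (c >= 1)."""
    n_tasks = int(rng.integers(1, max_tasks + 1))
    # demands sum to D >= 1 with |A| in [D, max_workers]
    while True:
        demands = rng.integers(0, 3, size=n_tasks)
        total = int(demands.sum())
        if 1 <= total <= max_workers:
            break
    n_workers = int(rng.integers(total, max_workers + 1))
    # random feasible initial allocation
    initial = np.zeros(n_tasks, dtype=int)
    spare = n_workers
    for i in range(n_tasks):
        initial[i] = int(rng.integers(0, spare + 1))
        spare -= initial[i]
    return make_scenario(tuple(demands), n_workers, tuple(initial))


def random_small_scenario(rng: np.random.Generator):
    """A random mid-size instance for invariant fuzzing."""
    n_tasks = int(rng.integers(1, 7))
    demands = rng.integers(0, 8, size=n_tasks)
    if demands.sum() == 0:
        demands[0] = 1
    total = int(demands.sum())
    n_workers = int(rng.integers(total, 2 * total + 5))
    initial = np.zeros(n_tasks, dtype=int)
    spare = n_workers
    for i in rng.permutation(n_tasks):
        initial[i] = int(rng.integers(0, min(spare, 10) + 1))
        spare -= initial[i]
    return make_scenario(tuple(demands), n_workers, tuple(initial))
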