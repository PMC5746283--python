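"""Colony state and the deterministic success-feedback semantics of one round.

The model: a colony of ``n_workers`` identical, memoryless workers must cover
a vector of integer task demands ``d_i`` (worker units of work per round).
A task is *satisfied* at time ``r`` when the worker count on it, ``w_i(r)``,
is at least ``d_i``.  Each synchronous round the environment tells exactly
``min(d_i, w_i)`` workers on task ``i`` that their work was needed ("musical
chairs" success feedback); everyone else — the idle plus the unsuccessful —
is *inactive* and must redraw a task from a choice distribution.

Because workers are identical and keep no history, per-task counts plus the
idle count are a sufficient statistic for the whole colony; no per-worker
state is tracked anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Scenario",
    "AllocationState",
    "RoundSplit",
    "make_scenario",
    "deficit_profile",
    "success_split",
    "apply_joiners",
    "inactive_count",
]


@dataclass(frozen=True)
class Scenario:
    """An allocation problem instance.

    Attributes
    ----------
    demands
        Integer work units ``d_i`` required by each task.
    n_workers
        Colony size ``|A|``; must be at least the total demand ``D`` so that
        the surplus ratio ``c = |A| / D`` is >= 1.
    initial_allocation
        Worker counts per task at time 0; the remainder of the colony starts
        idle.
    label
        Free-text name used in reports.
    """

    demands: tuple[int, ...]
    n_workers: int
    initial_allocation: tuple[int, ...]
    label: str = ""

    @property
    def n_tasks(self) -> int:
        return len(self.demands)

    @property
    def total_demand(self) -> int:
        """Total demand D = sum of d_i."""
        return int(sum(self.demands))

    @property
    def c(self) -> float:
        """Worker surplus ratio c = |A| / D (>= 1 by construction)."""
        return self.n_workers / self.total_demand

    @property
    def initial_idle(self) -> int:
        return self.n_workers - int(sum(self.initial_allocation))

    def initial_state(self) -> "AllocationState":
        return AllocationState(
            time=0,
            counts=np.asarray(self.initial_allocation, dtype=np.int64),
            idle=self.initial_idle,
        )


@dataclass
class AllocationState:
    """Worker counts per task plus the idle count at a point in time.

    Invariant: ``counts.sum() + idle == n_workers`` of the owning scenario
    (checked by every operation that receives both).
    """

    time: int
    counts: np.ndarray
    idle: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.idle < 0:
            raise ValueError("idle count must be >= 0")
        if (self.counts < 0).any():
            raise ValueError("worker counts must be >= 0")

    def total_workers(self) -> int:
        return int(self.counts.sum()) + self.idle


@dataclass
class RoundSplit:
    """Partition of the colony after success feedback in one round.

    ``retained[i]`` workers on task ``i`` received success bit 1 and stay;
    ``unsuccessful[i]`` workers on task ``i`` received 0 (excess over demand);
    ``idle_pool`` idle workers also received 0.  The *pool* — everyone who
    redraws a task this round — is ``unsuccessful.sum() + idle_pool``.

    ``idle_locked`` is only nonzero under success-bit noise: an idle worker
    whose bit was flipped to 1 keeps its (empty) state and does not redraw.
    Noise may also push ``retained[i]`` above ``d_i`` (a fake success on an
    oversubscribed task), so the ``retained <= d`` cap is a property of the
    noise-free split, not a structural invariant.
    """

    retained: np.ndarray
    unsuccessful: np.ndarray
    idle_pool: int
    idle_locked: int = 0

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=np.int64)
        self.unsuccessful = np.asarray(self.unsuccessful, dtype=np.int64)
        if (self.retained < 0).any() or (self.unsuccessful < 0).any():
            raise ValueError("split counts must be >= 0")
        if self.idle_pool < 0 or self.idle_locked < 0:
            raise ValueError("idle counts must be >= 0")

    @property
    def pool(self) -> int:
        """Number of inactive workers who redraw a task this round."""
        return int(self.unsuccessful.sum()) + self.idle_pool

    def total_workers(self) -> int:
        return int(self.retained.sum()) + self.pool + self.idle_locked


def make_scenario(
    demands,
    n_workers: int,
    initial_allocation="all-idle",
    label: str = "",
) -> Scenario:
    """Validate and build a :class:`Scenario`.

    ``initial_allocation="all-idle"`` places every worker in the idle state.
    Rejects negative demands, total demand of zero, colonies smaller than the
    total demand (surplus ratio c would be < 1), and initial allocations that
    use more workers than the colony has.
    """
    demands = tuple(int(d) for d in demands)
    if len(demands) == 0:
        raise ValueError("at least one task is required")
    if any(d < 0 for d in demands):
        raise ValueError("demands must be >= 0")
    total = sum(demands)
    if total < 1:
        raise ValueError("total demand must be >= 1")
    n_workers = int(n_workers)
    if n_workers < total:
        raise ValueError(
            f"n_workers={n_workers} < total demand D={total}: "
            "surplus ratio c = |A|/D must be >= 1"
        )
    if isinstance(initial_allocation, str):
        if initial_allocation != "all-idle":
            raise ValueError(f"unknown initial allocation {initial_allocation!r}")
        initial = (0,) * len(demands)
    else:
        initial = tuple(int(w) for w in initial_allocation)
        if len(initial) != len(demands):
            raise ValueError("initial allocation length must match demands")
        if any(w < 0 for w in initial):
            raise ValueError("initial allocation counts must be >= 0")
        if sum(initial) > n_workers:
            raise ValueError("initial allocation exceeds colony size")
    return Scenario(demands=demands, n_workers=n_workers,
                    initial_allocation=initial, label=label)


def _check_consistent(state: AllocationState, scenario: Scenario) -> None:
    if len(state.counts) != scenario.n_tasks:
        raise ValueError("state has wrong number of tasks for scenario")
    if state.total_workers() != scenario.n_workers:
        raise ValueError(
            f"worker conservation violated: state holds {state.total_workers()} "
            f"workers, scenario has {scenario.n_workers}"
        )


def deficit_profile(state: AllocationState, scenario: Scenario):
    """Per-task deficits, total deficit, and the (un)satisfied task sets.

    Returns ``(phi_i, phi, unsatisfied, satisfied)`` where
    ``phi_i = max(0, d_i - w_i)``, ``phi = sum(phi_i)``, and the sets are
    index arrays of tasks with ``d_i > w_i`` resp. ``d_i <= w_i``.
    """
    _check_consistent(state, scenario)
    d = np.asarray(scenario.demands, dtype=np.int64)
    phi_i = np.maximum(0, d - state.counts)
    unsat = np.flatnonzero(phi_i > 0)
    sat = np.flatnonzero(phi_i == 0)
    return phi_i, int(phi_i.sum()), unsat, sat


def success_split(state: AllocationState, scenario: Scenario) -> RoundSplit:
    """Apply noise-free success feedback: min(d_i, w_i) workers are retained.

    Which individuals are retained is immaterial (identical memoryless
    workers), so the counts fully specify the split.
    """
    _check_consistent(state, scenario)
    d = np.asarray(scenario.demands, dtype=np.int64)
    retained = np.minimum(d, state.counts)
    unsuccessful = state.counts - retained
    return RoundSplit(retained=retained, unsuccessful=unsuccessful,
                      idle_pool=state.idle)


def apply_joiners(
    state: AllocationState,
    split: RoundSplit,
    joiners,
    idle_joiners: int,
) -> AllocationState:
    """Advance one round: pool members adopt their drawn tasks (or idle).

    ``joiners[i]`` pool members join task ``i``; ``idle_joiners`` drew the
    bottom symbol and go idle.  The counts must exhaust the pool exactly.
    """
    joiners = np.asarray(joiners, dtype=np.int64)
    if (joiners < 0).any() or idle_joiners < 0:
        raise ValueError("joiner counts must be >= 0")
    if int(joiners.sum()) + int(idle_joiners) != split.pool:
        raise ValueError(
            f"joiners ({int(joiners.sum())} + {idle_joiners} idle) "
            f"do not exhaust the pool of {split.pool}"
        )
    return AllocationState(
        time=state.time + 1,
        counts=split.retained + joiners,
        idle=int(idle_joiners) + split.idle_locked,
    )


def inactive_count(state: AllocationState, scenario: Scenario) -> int:
    """Workers that will be inactive in the next round: |A| - sum min(d_i, w_i).

    For any consistent state this equals Phi(r) + (c-1)D and is therefore at
    least c * Phi(r) whenever c >= 1 (the surplus guarantee the convergence
    proofs rest on); the test suite asserts the inequality on every round
    rather than assuming it.
    """
    _check_consistent(state, scenario)
    d = np.asarray(scenario.demands, dtype=np.int64)
    return scenario.n_workers - int(np.minimum(d, state.counts).sum())
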