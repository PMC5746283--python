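"""Seeded synchronous-round executions and replicated completion statistics.

One round, computed entirely from the time-r state (synchronous semantics):

1. success feedback retains min(d_i, w_i) workers per task;
2. optional success-bit noise flips at most z bits;
3. the choice distribution is built from the *unflipped* time-r state
   (the choice component does not see the success mistakes);
4. optional choice noise perturbs it within the (1-y) floor;
5. every pool member draws a task (or bottom) independently — one
   multinomial — and all transitions are applied at once.

Noise-free runs stop as soon as the total deficit hits zero (satisfaction is
absorbing: deficits and the unsatisfied-task count never increase).  Noisy
runs execute the full horizon and additionally report the minimum deficit
seen, since bit flips can re-create deficit after it first vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .choice import (ChoiceOption, ChoiceSpec, apply_success_noise,
                     choice_distribution, perturb_choice_distribution,
                     sample_joiners)
from .model import (AllocationState, Scenario, apply_joiners, deficit_profile,
                    inactive_count, success_split)

__all__ = [
    "RoundRecord",
    "Trajectory",
    "ReplicationSummary",
    "run",
    "completion_round",
    "epsilon_round",
    "replicate",
]


@dataclass(frozen=True)
class RoundRecord:
    round: int
    phi_total: int
    n_unsatisfied: int
    n_idle: int
    n_inactive: int


@dataclass
class Trajectory:
    """Per-round record of one seeded execution."""

    scenario: Scenario
    spec: ChoiceSpec
    seed: int
    records: list[RoundRecord]
    completion_round: int | None
    final_counts: np.ndarray
    final_idle: int
    counts_series: list[np.ndarray] | None = None

    @property
    def phi_series(self) -> np.ndarray:
        return np.array([rec.phi_total for rec in self.records])

    @property
    def min_phi(self) -> int:
        return int(self.phi_series.min())

    def first_round_below(self, threshold: float) -> int | None:
        """First round r with Phi(r) <= threshold, or None within horizon."""
        hits = np.flatnonzero(self.phi_series <= threshold)
        return int(hits[0]) if len(hits) else None


def run(
    scenario: Scenario,
    spec: ChoiceSpec,
    max_rounds: int,
    seed: int,
    record_counts: bool = False,
) -> Trajectory:
    """Execute one seeded run of at most ``max_rounds`` rounds.

    Noise-free executions stop at the first round with zero total deficit
    (recorded as ``completion_round``); an execution that never reaches it
    within the horizon reports ``completion_round=None``.  All randomness
    derives from ``seed`` alone.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    rng = np.random.default_rng(seed)
    state = scenario.initial_state()
    records: list[RoundRecord] = []
    counts_series: list[np.ndarray] | None = [] if record_counts else None
    completion: int | None = None

    def record(st: AllocationState) -> int:
        phi_i, phi, unsat, _ = deficit_profile(st, scenario)
        records.append(RoundRecord(
            round=st.time, phi_total=phi, n_unsatisfied=len(unsat),
            n_idle=st.idle, n_inactive=inactive_count(st, scenario)))
        if counts_series is not None:
            counts_series.append(st.counts.copy())
        return phi

    phi = record(state)
    if phi == 0:
        completion = 0
    settled = False
    while state.time < max_rounds:
        if completion is not None and not spec.noisy:
            # Under the informed options the post-completion round is
            # deterministic: choice returns bottom, so excess workers shed
            # to idle and the state becomes a true fixed point.  Execute
            # that one settlement round, then stop.
            pool = success_split(state, scenario).pool
            if settled or spec.option == ChoiceOption.UNIFORM_ALL or pool == 0:
                break
            settled = True
        split = success_split(state, scenario)
        if spec.z > 0:
            split = apply_success_noise(split, state, scenario, spec.z,
                                        spec.adversary, rng)
        dist = choice_distribution(state, scenario, spec)
        if spec.y > 0.0:
            dist = perturb_choice_distribution(dist, spec.y, spec.adversary,
                                               rng)
        joiners, idle_joiners = sample_joiners(split.pool, dist, rng)
        state = apply_joiners(state, split, joiners, idle_joiners)
        phi = record(state)
        if phi == 0 and completion is None:
            completion = state.time
    return Trajectory(scenario=scenario, spec=spec, seed=seed,
                      records=records, completion_round=completion,
                      final_counts=state.counts.copy(), final_idle=state.idle,
                      counts_series=counts_series)


def completion_round(traj: Trajectory) -> int | None:
    """First round with zero total deficit, or None within the horizon."""
    return traj.first_round_below(0)


def epsilon_round(traj: Trajectory, epsilon: float) -> int | None:
    """First round r with Phi(r) <= epsilon * Phi(0)."""
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError("epsilon must be in [0, 1]")
    phi0 = traj.records[0].phi_total
    return traj.first_round_below(epsilon * phi0)


def _inverse_ecdf_quantile(sorted_values: np.ndarray, q: float) -> float:
    """Type-1 (inverse ECDF) quantile of an already-sorted sample."""
    n = len(sorted_values)
    k = max(1, math.ceil(q * n))
    return float(sorted_values[k - 1])


@dataclass
class ReplicationSummary:
    """Completion-time statistics over independent seeded runs.

    Runs that never complete within the horizon enter the order statistics
    as +inf so high quantiles faithfully report non-completion.
    """

    n_runs: int
    base_seed: int
    completion_rounds: np.ndarray
    epsilon: float | None = None
    epsilon_rounds: np.ndarray | None = None
    min_phis: np.ndarray | None = None

    def quantile(self, q: float) -> float:
        """Inverse-ECDF (order statistic) quantile of completion rounds."""
        if not (0.0 < q <= 1.0):
            raise ValueError("quantile level must be in (0, 1]")
        return _inverse_ecdf_quantile(np.sort(self.completion_rounds), q)

    def epsilon_quantile(self, q: float) -> float:
        if self.epsilon_rounds is None:
            raise ValueError("no epsilon threshold was requested")
        return _inverse_ecdf_quantile(np.sort(self.epsilon_rounds), q)

    def prob_complete_by(self, t: float) -> float:
        """Empirical P(completion round <= t)."""
        return float(np.mean(self.completion_rounds <= t))

    @property
    def max_round(self) -> float:
        return float(self.completion_rounds.max())

    @property
    def mean_round(self) -> float:
        return float(self.completion_rounds.mean())

    @property
    def median_round(self) -> float:
        return self.quantile(0.5)

    def to_dict(self, ts: tuple[int, ...] = ()) -> dict:
        out = {
            "n_runs": self.n_runs,
            "base_seed": self.base_seed,
            "quantiles": {f"q{int(q * 100)}": self.quantile(q)
                          for q in (0.5, 0.8, 0.9, 0.95)},
            "max": self.max_round,
        }
        if np.isfinite(self.completion_rounds).all():
            out["mean"] = self.mean_round
        out["p_complete_by"] = {str(int(t)): self.prob_complete_by(t)
                                for t in ts}
        if self.epsilon_rounds is not None:
            out["epsilon"] = self.epsilon
            out["epsilon_quantiles"] = {
                f"q{int(q * 100)}": self.epsilon_quantile(q)
                for q in (0.5, 0.8, 0.9, 0.95)}
        return out


def replicate(
    scenario: Scenario,
    spec: ChoiceSpec,
    n_runs: int,
    base_seed: int,
    max_rounds: int,
    epsilon: float | None = None,
) -> ReplicationSummary:
    """Run ``n_runs`` independent executions with seeds base_seed + i."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    completions = np.empty(n_runs)
    eps_rounds = np.empty(n_runs) if epsilon is not None else None
    min_phis = np.empty(n_runs, dtype=np.int64)
    for i in range(n_runs):
        traj = run(scenario, spec, max_rounds=max_rounds, seed=base_seed + i)
        cr = traj.completion_round
        completions[i] = np.inf if cr is None else cr
        min_phis[i] = traj.min_phi
        if eps_rounds is not None:
            er = epsilon_round(traj, epsilon)
            eps_rounds[i] = np.inf if er is None else er
    return ReplicationSummary(
        n_runs=n_runs, base_seed=base_seed, completion_rounds=completions,
        epsilon=epsilon, epsilon_rounds=eps_rounds, min_phis=min_phis)
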