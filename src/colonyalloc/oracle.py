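"""Exact absorbing-Markov-chain analysis of tiny allocation instances.

Worker exchangeability means the process on count vectors (w_1..w_|T|, idle)
is itself Markov: states are the compositions of |A| into |T|+1 cells, and
the one-round kernel is the exact multinomial distribution of the pool's
joiner split applied after success feedback.  States with zero total deficit
are absorbing in the noise-free process.

This module is the brute-force ground truth for the stochastic simulator:
hitting-time CDFs and expected-deficit series are computed by iterated
kernel application and compared to Monte-Carlo estimates via the
Dvoretzky-Kiefer-Wolfowitz band.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.stats import multinomial as sp_multinomial

from .choice import (ChoiceSpec, apply_success_noise, choice_distribution,
                     perturb_choice_distribution)
from .model import AllocationState, Scenario, deficit_profile, success_split
from .simulate import ReplicationSummary

__all__ = [
    "ChainModel",
    "build_chain",
    "hitting_time_cdf",
    "expected_deficit",
    "dkw_band",
    "validate_montecarlo",
    "MonteCarloReport",
]

DEFAULT_STATE_CAP = 200_000


def _compositions(total: int, cells: int):
    """All ways to place ``total`` identical workers into ``cells`` cells."""
    if cells == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for rest in _compositions(total - head, cells - 1):
            yield (head,) + rest


@dataclass
class ChainModel:
    """Enumerated state space and exact one-round transition kernel."""

    scenario: Scenario
    spec: ChoiceSpec
    states: list[tuple[int, ...]]          # (w_1..w_T, idle) compositions
    index: dict[tuple[int, ...], int]
    kernel: sparse.csr_matrix
    phi: np.ndarray                        # total deficit per state
    absorbing: np.ndarray                  # boolean mask, phi == 0

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, counts, idle: int) -> int:
        key = tuple(int(x) for x in counts) + (int(idle),)
        return self.index[key]

    def start_index(self) -> int:
        s = self.scenario.initial_state()
        return self.state_index(s.counts, s.idle)


def build_chain(
    scenario: Scenario,
    spec: ChoiceSpec,
    max_states: int = DEFAULT_STATE_CAP,
) -> ChainModel:
    """Enumerate the count-state space and assemble the exact kernel.

    The state count is C(|A| + |T|, |T|); instances above ``max_states``
    are rejected with a size report.  Randomised noise policies are excluded
    (the kernel must be a deterministic function of the state), but the
    deterministic policies (uniform_shift, suppress_success, fake_success)
    are supported.
    """
    n, a = scenario.n_tasks, scenario.n_workers
    size = math.comb(a + n, n)
    if size > max_states:
        raise ValueError(
            f"state space has {size} states (> cap {max_states}); "
            "exact analysis is restricted to tiny instances")
    if spec.adversary == "random":
        raise ValueError("randomised noise policies have no deterministic "
                         "kernel; use a deterministic policy")
    states = list(_compositions(a, n + 1))
    index = {s: i for i, s in enumerate(states)}
    d = np.asarray(scenario.demands, dtype=np.int64)
    phi = np.array([int(np.maximum(0, d - np.array(s[:-1])).sum())
                    for s in states], dtype=np.int64)
    absorbing = phi == 0

    rows, cols, vals = [], [], []
    for si, s in enumerate(states):
        counts, idle = np.array(s[:-1], dtype=np.int64), s[-1]
        state = AllocationState(time=0, counts=counts, idle=idle)
        if absorbing[si] and not spec.noisy:
            rows.append(si)
            cols.append(si)
            vals.append(1.0)
            continue
        split = success_split(state, scenario)
        if spec.z > 0:
            split = apply_success_noise(split, state, scenario, spec.z,
                                        spec.adversary, rng=None)
        dist = choice_distribution(state, scenario, spec)
        if spec.y > 0.0:
            dist = perturb_choice_distribution(dist, spec.y, spec.adversary)
        p_full = dist.full()
        pool = split.pool
        if pool == 0:
            dest = tuple(int(x) for x in split.retained) + \
                (int(split.idle_locked),)
            rows.append(si)
            cols.append(index[dest])
            vals.append(1.0)
            continue
        for joiners in _compositions(pool, n + 1):
            prob = float(sp_multinomial.pmf(joiners, n=pool, p=p_full))
            if prob <= 0.0:
                continue
            new_counts = split.retained + np.array(joiners[:-1],
                                                   dtype=np.int64)
            new_idle = joiners[-1] + split.idle_locked
            dest = tuple(int(x) for x in new_counts) + (int(new_idle),)
            rows.append(si)
            cols.append(index[dest])
            vals.append(prob)
    kernel = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(states), len(states)))
    row_sums = np.asarray(kernel.sum(axis=1)).ravel()
    if not np.allclose(row_sums, 1.0, atol=1e-12):
        raise AssertionError("kernel rows do not sum to 1")
    return ChainModel(scenario=scenario, spec=spec, states=states,
                      index=index, kernel=kernel, phi=phi,
                      absorbing=absorbing)


def hitting_time_cdf(
    chain: ChainModel, start: int | None = None, horizon: int = 50
) -> np.ndarray:
    """Exact P(completion time <= t) for t = 0..horizon.

    Completion time is the first round at which the total deficit is zero;
    the CDF is the mass on the absorbing set after iterated kernel
    application (absorbing states self-loop, so the mass is cumulative).
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if start is None:
        start = chain.start_index()
    mu = np.zeros(chain.n_states)
    mu[start] = 1.0
    cdf = np.empty(horizon + 1)
    cdf[0] = mu[chain.absorbing].sum()
    for t in range(1, horizon + 1):
        mu = mu @ chain.kernel
        cdf[t] = mu[chain.absorbing].sum()
    return cdf


def expected_deficit(
    chain: ChainModel, start: int | None = None, horizon: int = 50
) -> np.ndarray:
    """Exact E[Phi(r)] for r = 0..horizon."""
    if start is None:
        start = chain.start_index()
    mu = np.zeros(chain.n_states)
    mu[start] = 1.0
    out = np.empty(horizon + 1)
    out[0] = float(mu @ chain.phi)
    for t in range(1, horizon + 1):
        mu = mu @ chain.kernel
        out[t] = float(mu @ chain.phi)
    return out


def dkw_band(n: int, alpha: float) -> float:
    """Dvoretzky-Kiefer-Wolfowitz sup-norm band sqrt(ln(2/alpha) / (2n))."""
    if n < 1 or not (0.0 < alpha < 1.0):
        raise ValueError("need n >= 1 and alpha in (0, 1)")
    return math.sqrt(math.log(2.0 / alpha) / (2.0 * n))


@dataclass(frozen=True)
class MonteCarloReport:
    max_discrepancy: float
    band: float
    n_runs: int
    alpha: float

    @property
    def passed(self) -> bool:
        return self.max_discrepancy <= self.band


def validate_montecarlo(
    chain: ChainModel,
    summary: ReplicationSummary,
    alpha: float = 0.01,
    horizon: int | None = None,
) -> MonteCarloReport:
    """Compare an empirical completion CDF against the exact chain CDF.

    The sup-norm distance over t = 0..horizon is compared to the DKW band
    at confidence 1 - alpha; the empirical CDF of n i.i.d. runs exceeds the
    band with probability at most alpha when the two laws coincide.
    """
    completions = summary.completion_rounds
    if horizon is None:
        finite = completions[np.isfinite(completions)]
        horizon = int(finite.max()) + 1 if len(finite) else 1
    exact = hitting_time_cdf(chain, horizon=horizon)
    ts = np.arange(horizon + 1)
    empirical = np.array([np.mean(completions <= t) for t in ts])
    dist = float(np.abs(empirical - exact).max())
    return MonteCarloReport(max_discrepancy=dist,
                            band=dkw_band(summary.n_runs, alpha),
                            n_runs=summary.n_runs, alpha=alpha)
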