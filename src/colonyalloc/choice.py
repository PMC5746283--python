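"""Choice-feedback distributions and the noise perturbations.

Three choice options are modelled, differing in how much an inactive worker
can sense about demand elsewhere in the nest:

1. ``UNIFORM_ALL`` — a uniformly random task (no demand information).
2. ``UNIFORM_UNSAT`` — uniform over the currently unsatisfied tasks.
3. ``DEFICIT_WEIGHTED`` — an unsatisfied task i with probability
   Phi_i(r) / Phi(r) (workers sense stimulus proportional to unmet demand).

Options 2 and 3 return the bottom symbol (stay idle) with probability 1 when
every task is satisfied.

Noise (analysed for option 3 only): the choice distribution may be perturbed
to anything that keeps each unsatisfied task's probability at least
``(1-y)`` times its nominal deficit-weighted mass, and the success component
may flip the 0/1 bits of at most ``z`` workers per round.  The admissible
perturbation/flip is adversarial; concrete seeded policies are defined here
so noisy runs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .model import AllocationState, RoundSplit, Scenario, deficit_profile

__all__ = [
    "ChoiceOption",
    "ChoiceSpec",
    "ChoiceDistribution",
    "choice_distribution",
    "perturb_choice_distribution",
    "apply_success_noise",
    "sample_joiners",
]

_MASS_TOL = 1e-12

CHOICE_ADVERSARIES = ("none", "random", "suppress_success", "fake_success",
                      "uniform_shift")


class ChoiceOption(IntEnum):
    UNIFORM_ALL = 1
    UNIFORM_UNSAT = 2
    DEFICIT_WEIGHTED = 3


@dataclass(frozen=True)
class ChoiceSpec:
    """Choice option plus noise parameters.

    ``y`` in [0,1) bounds the multiplicative slack on choice probabilities;
    ``z`` is the per-round budget of flipped success bits; ``adversary``
    names the concrete policy realising them.  Noise-free specs must have
    y = 0 and z = 0.  Noise is only analysed for option 3; other
    combinations are permitted but warned about.
    """

    option: ChoiceOption
    y: float = 0.0
    z: int = 0
    adversary: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "option", ChoiceOption(self.option))
        if not (0.0 <= self.y < 1.0):
            raise ValueError("choice-noise parameter y must be in [0, 1)")
        if self.z < 0:
            raise ValueError("success-noise budget z must be >= 0")
        if self.adversary not in CHOICE_ADVERSARIES:
            raise ValueError(f"unknown adversary policy {self.adversary!r}")
        if self.adversary == "none" and (self.y != 0.0 or self.z != 0):
            raise ValueError("noise parameters require an adversary policy")
        if self.adversary != "none" and self.y == 0.0 and self.z == 0:
            raise ValueError("adversary policy given but y = z = 0")
        if self.noisy and self.option != ChoiceOption.DEFICIT_WEIGHTED:
            warnings.warn(
                "noise guarantees are only analysed for the deficit-weighted "
                "option (3); running it on option "
                f"{int(self.option)} is unvalidated",
                stacklevel=2,
            )

    @property
    def noisy(self) -> bool:
        return self.y > 0.0 or self.z > 0


@dataclass
class ChoiceDistribution:
    """Probabilities over tasks plus a bottom (stay-idle) mass."""

    probabilities: np.ndarray
    bottom: float = 0.0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if (self.probabilities < 0).any() or self.bottom < 0:
            raise ValueError("choice distribution has negative mass")
        total = float(self.probabilities.sum()) + self.bottom
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"choice distribution mass {total} != 1")

    def full(self) -> np.ndarray:
        """Task probabilities with the bottom mass appended."""
        return np.append(self.probabilities, self.bottom)


def choice_distribution(
    state: AllocationState, scenario: Scenario, spec: ChoiceSpec
) -> ChoiceDistribution:
    """Nominal (noise-free) choice distribution for the current state."""
    phi_i, phi, unsat, _ = deficit_profile(state, scenario)
    n = scenario.n_tasks
    if spec.option == ChoiceOption.UNIFORM_ALL:
        return ChoiceDistribution(np.full(n, 1.0 / n), bottom=0.0)
    if phi == 0:
        return ChoiceDistribution(np.zeros(n), bottom=1.0)
    probs = np.zeros(n)
    if spec.option == ChoiceOption.UNIFORM_UNSAT:
        probs[unsat] = 1.0 / len(unsat)
    else:  # DEFICIT_WEIGHTED
        probs = phi_i / phi
    return ChoiceDistribution(probs, bottom=0.0)


def perturb_choice_distribution(
    dist: ChoiceDistribution,
    y: float,
    adversary: str,
    rng: np.random.Generator | None = None,
    target: ChoiceDistribution | None = None,
) -> ChoiceDistribution:
    """Perturb a deficit-weighted distribution within the (1-y) floor.

    Every task with nominal mass p_i must keep probability >= (1-y) * p_i;
    the freed mass (at most y) is re-assigned by the adversary policy:

    * ``uniform_shift`` — spread uniformly over the unsatisfied tasks
      (deterministic);
    * ``random`` — a seeded random re-weighting of the freed mass.

    If an explicit ``target`` distribution is supplied it is validated
    against the floor and returned; targets below the floor are rejected.
    """
    if not (0.0 <= y < 1.0):
        raise ValueError("y must be in [0, 1)")
    base = dist.probabilities
    floor = (1.0 - y) * base
    if target is not None:
        if len(target.probabilities) != len(base):
            raise ValueError("target distribution has wrong length")
        if (target.probabilities < floor - _MASS_TOL).any():
            raise ValueError(
                "target distribution violates the (1-y) probability floor"
            )
        return target
    if y == 0.0:
        return dist
    if dist.bottom >= 1.0 - _MASS_TOL:
        return dist  # all satisfied; nothing to perturb
    support = base > 0
    freed = 1.0 - dist.bottom - float(floor.sum())
    probs = floor.copy()
    if adversary == "uniform_shift" or adversary == "none":
        probs[support] += freed / support.sum()
    elif adversary == "random":
        if rng is None:
            raise ValueError("random adversary requires a seeded rng")
        weights = rng.dirichlet(np.ones(int(support.sum())))
        probs[support] += freed * weights
    elif adversary in ("suppress_success", "fake_success"):
        # success-bit policies leave the choice distribution nominal
        probs[support] += freed / support.sum()
    else:
        raise ValueError(f"unknown adversary policy {adversary!r}")
    return ChoiceDistribution(probs, bottom=dist.bottom)


def apply_success_noise(
    split: RoundSplit,
    state: AllocationState,
    scenario: Scenario,
    z: int,
    adversary: str,
    rng: np.random.Generator | None = None,
) -> RoundSplit:
    """Flip the success bits of at most ``z`` workers.

    * ``suppress_success`` — up to z retained workers (highest-deficit tasks
      first) are told 0 and join the pool; the colony can lose ground.
    * ``fake_success`` — up to z pool members are told 1 and stay put:
      unsuccessful excess workers remain on their (oversubscribed) task,
      idle workers simply stay idle without redrawing.
    * ``random`` — a uniform sample of z workers over the whole colony has
      its bit flipped (1->0 for retained, 0->1 for pool members).

    Budgets beyond the feasible number of flips are clipped.  Worker
    conservation holds by construction.
    """
    if z < 0 or z > scenario.n_workers:
        raise ValueError("z must be in [0, |A|]")
    if z == 0 or adversary == "none":
        return split
    d = np.asarray(scenario.demands, dtype=np.int64)
    retained = split.retained.copy()
    unsuccessful = split.unsuccessful.copy()
    idle_pool = split.idle_pool
    idle_locked = split.idle_locked

    if adversary in ("suppress_success", "uniform_shift"):
        # uniform_shift is a choice-only policy; its success bits are honest
        if adversary == "uniform_shift":
            return split
        deficits = np.maximum(0, d - state.counts)
        order = np.argsort(-deficits, kind="stable")
        budget = z
        for i in order:
            if budget == 0:
                break
            take = min(budget, int(retained[i]))
            retained[i] -= take
            unsuccessful[i] += take
            budget -= take
    elif adversary == "fake_success":
        budget = z
        # keep excess workers on their tasks first, then lock idle workers
        for i in np.argsort(-unsuccessful, kind="stable"):
            if budget == 0:
                break
            take = min(budget, int(unsuccessful[i]))
            unsuccessful[i] -= take
            retained[i] += take
            budget -= take
        take = min(budget, idle_pool)
        idle_pool -= take
        idle_locked += take
    elif adversary == "random":
        if rng is None:
            raise ValueError("random adversary requires a seeded rng")
        n = scenario.n_tasks
        # categories: retained per task, unsuccessful per task, idle pool
        sizes = np.concatenate([retained, unsuccessful, [idle_pool]])
        total = int(sizes.sum())
        flips = min(z, total)
        chosen = rng.multivariate_hypergeometric(sizes.astype(np.int64), flips)
        retained = retained - chosen[:n] + chosen[n:2 * n]
        unsuccessful = unsuccessful + chosen[:n] - chosen[n:2 * n]
        idle_pool -= int(chosen[2 * n])
        idle_locked += int(chosen[2 * n])
    else:
        raise ValueError(f"unknown adversary policy {adversary!r}")
    return RoundSplit(retained=retained, unsuccessful=unsuccessful,
                      idle_pool=idle_pool, idle_locked=idle_locked)


def sample_joiners(
    pool: int, dist: ChoiceDistribution, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """One multinomial draw of the pool over (tasks, bottom).

    Each pool member draws its new task independently from the shared
    per-round distribution, so the joint joiner counts are multinomial with
    ``E[joiners_i] = pool * dist_i``.
    """
    if pool < 0:
        raise ValueError("pool must be >= 0")
    full = dist.full()
    if pool == 0:
        return np.zeros(len(dist.probabilities), dtype=np.int64), 0
    draw = rng.multinomial(pool, full / full.sum())
    return draw[:-1].astype(np.int64), int(draw[-1])
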