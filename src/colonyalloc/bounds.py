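"""Analytic high-probability upper bounds on the time to re-allocate.

All bounds are on the number of synchronous rounds until every task demand
is met (or, in the epsilon-forms, until at most an ``epsilon`` fraction of
the initial total deficit remains), each holding with probability at least
``1 - delta`` over the choice randomness, for *any* initial configuration.

Option (1), uniform choice over all tasks, has an exact non-asymptotic form

    K1 * (|T| / c) * (ln Phi(0) + ln(1/delta)),        K1 = 8,

whose constant is frozen by requiring it to reproduce all published
numerical evaluations of the bound simultaneously (seven values, matched to
better than 0.01).  The epsilon-form replaces ln Phi(0) by ln(1/epsilon).

Options (2) and (3) (uniform over unsatisfied tasks; deficit-weighted) are
min-forms capped at |T| — with informed choice every round satisfies at
least one task, so |T| rounds always suffice regardless of the deficit.
Their leading constants are not published in non-asymptotic form; they
default to 1 and are exposed as parameters, and the package validates these
options primarily by simulation against the |T| cap.

The noisy deficit-weighted bound (choice slack y, success-flip budget z)
guarantees only a residual deficit <= z.  For c >= 1 its rate comes from the
per-round contraction of the expected deficit to (3+y)/4 of its value, so
the default branch is (ln Phi(0) + ln(1/delta)) / ln(4/(3+y)); for c > 1
the surplus workers cancel the effect of y and the branch is (1/c) times
the log term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BoundResult",
    "K1_UNIFORM",
    "bound_option1",
    "bound_option2",
    "bound_option3",
    "bound_option3_noisy",
    "bound_for_option",
    "sweep_bounds",
]

#: Multiplicative constant of the exact option-(1) bound, frozen by fitting
#: the published numerical evaluations of the bound (six full-satisfaction
#: values, five epsilon-values and one sweep intercept agree to < 0.01).
K1_UNIFORM = 8.0


@dataclass(frozen=True)
class BoundResult:
    """A rounds-valued upper bound plus which branch of the min was active."""

    rounds: float
    form: str
    provenance: str

    def __float__(self) -> float:
        return self.rounds


def _validate(n_tasks: int, c: float, phi0: float | None, delta: float,
              epsilon: float | None) -> None:
    if n_tasks < 1:
        raise ValueError("n_tasks must be >= 1")
    if c < 1.0:
        raise ValueError("surplus ratio c must be >= 1")
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must be in (0, 1)")
    if epsilon is None:
        if phi0 is None or phi0 < 1.0:
            raise ValueError("full-satisfaction bounds require phi0 >= 1")
    else:
        if epsilon == 0.0:
            raise ValueError(
                "epsilon=0 is the full-satisfaction case; omit epsilon")
        if not (0.0 < epsilon < 1.0):
            raise ValueError("epsilon must be in (0, 1)")


def _log_term(phi0: float | None, delta: float, epsilon: float | None) -> float:
    head = math.log(1.0 / epsilon) if epsilon is not None else math.log(phi0)
    return head + math.log(1.0 / delta)


def bound_option1(
    n_tasks: int,
    c: float,
    phi0: float | None,
    delta: float,
    epsilon: float | None = None,
    K1: float = K1_UNIFORM,
) -> BoundResult:
    """Exact uniform-choice bound K1 * (|T|/c) * (ln Phi0 + ln(1/delta)).

    With ``epsilon`` given, the approximate-satisfaction form replaces
    ln Phi0 by ln(1/epsilon): the remaining deficit is then at most
    epsilon * Phi(0) with probability 1 - delta.
    """
    _validate(n_tasks, c, phi0, delta, epsilon)
    rounds = K1 * (n_tasks / c) * _log_term(phi0, delta, epsilon)
    form = "epsilon" if epsilon is not None else "full"
    return BoundResult(rounds=rounds, form=form, provenance="uniform-choice")


def bound_option2(
    n_tasks: int,
    c: float,
    phi0: float | None,
    delta: float,
    epsilon: float | None = None,
    K2a: float = 1.0,
    K2b: float = 1.0,
) -> BoundResult:
    """Uniform-over-unsatisfied bound: min of the |T| cap, a log-deficit
    branch, and (for c > 1) a 1/ln(c) branch that diverges as c -> 1+."""
    _validate(n_tasks, c, phi0, delta, epsilon)
    log_term = _log_term(phi0, delta, epsilon)
    branches = {"cap": float(n_tasks), "log-deficit": K2a * log_term}
    if c > 1.0:
        head = math.log(1.0 / epsilon) if epsilon is not None \
            else math.log(n_tasks)
        branches["1/ln(c)"] = K2b * (head + math.log(1.0 / delta)) / math.log(c)
    form = min(branches, key=branches.get)
    return BoundResult(rounds=branches[form], form=form,
                       provenance="uniform-unsatisfied")


def bound_option3(
    n_tasks: int,
    c: float,
    phi0: float | None,
    delta: float,
    epsilon: float | None = None,
    K3a: float = 1.0,
    K3b: float = 1.0,
) -> BoundResult:
    """Deficit-weighted bound: min of the |T| cap, a log-deficit branch,
    and (for c > 1) the same branch accelerated by 1/c."""
    _validate(n_tasks, c, phi0, delta, epsilon)
    log_term = _log_term(phi0, delta, epsilon)
    branches = {"cap": float(n_tasks), "log-deficit": K3a * log_term}
    if c > 1.0:
        branches["1/c"] = (K3b / c) * log_term
    form = min(branches, key=branches.get)
    return BoundResult(rounds=branches[form], form=form,
                       provenance="deficit-weighted")


def bound_option3_noisy(
    n_tasks: int,
    c: float,
    phi0: float,
    delta: float,
    y: float,
    K4a: float = 1.0,
    K4b: float = 1.0,
) -> BoundResult:
    """Noisy deficit-weighted bound; the contract is residual deficit <= z.

    For c >= 1 the expected deficit contracts to (3+y)/4 per round, giving
    K4a * (ln Phi0 + ln(1/delta)) / ln(4/(3+y)); this grows without bound
    as y -> 1- (the min then picks the |T| cap) and reduces to the
    noise-free logarithmic shape as y -> 0.  For c > 1 the branch is
    (K4b/c) * (ln Phi0 + ln(1/delta)) with no y dependence: the surplus
    workers cancel the effect of the choice slack.
    """
    if not (0.0 <= y < 1.0):
        raise ValueError("y must be in [0, 1)")
    _validate(n_tasks, c, phi0, delta, None)
    log_term = _log_term(phi0, delta, None)
    branches = {
        "cap": float(n_tasks),
        "noisy-contraction": K4a * log_term / math.log(4.0 / (3.0 + y)),
    }
    if c > 1.0:
        branches["1/c"] = (K4b / c) * log_term
    form = min(branches, key=branches.get)
    return BoundResult(rounds=branches[form], form=form,
                       provenance="deficit-weighted-noisy")


def bound_for_option(
    option: int,
    n_tasks: int,
    c: float,
    phi0: float | None,
    delta: float,
    epsilon: float | None = None,
    **constants,
) -> BoundResult:
    """Dispatch to the bound for a choice option (1, 2 or 3, noise-free)."""
    fn = {1: bound_option1, 2: bound_option2, 3: bound_option3}[int(option)]
    return fn(n_tasks, c, phi0, delta, epsilon, **constants)


def sweep_bounds(
    option: int,
    parameter: str,
    grid,
    n_tasks: int,
    phi0: float,
    c: float = 1.0,
    delta: float = 0.01,
    epsilon: float | None = None,
    **constants,
) -> pd.DataFrame:
    """Evaluate a bound along a grid of ``c`` or ``delta`` values.

    Returns a DataFrame with columns (parameter value, rounds, form).  The
    c-sweep of options (1)/(3) follows (value at c=1)/c; the option-(2)
    curve stays flat at its c=1 value until the 1/ln(c) branch undercuts it
    (roughly c >= e).
    """
    if parameter not in ("c", "delta"):
        raise ValueError("parameter must be 'c' or 'delta'")
    rows = []
    for x in np.asarray(grid, dtype=float):
        kwargs = dict(n_tasks=n_tasks, c=c, phi0=phi0, delta=delta,
                      epsilon=epsilon, **constants)
        kwargs[parameter] = float(x)
        res = bound_for_option(option, **kwargs)
        rows.append({parameter: float(x), "rounds": res.rounds,
                     "form": res.form})
    return pd.DataFrame(rows)
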