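# Methods

## Model

The system is a colony of `|A|` identical, memoryless workers and a static
integer demand vector `d = (d_1, ..., d_|T|)`, `D = Σ d_i ≥ 1`, `|A| = c·D`
with `c ≥ 1`.  Each worker is in one state per time step: working on some
task `i`, or idle.  Execution proceeds in synchronous rounds.  In round
`r+1`, computed entirely from the time-`r` state:

1. **Success feedback.**  On each task exactly `min(d_i, w_i(r))` workers
   receive bit 1 and keep their state; excess workers and all idle workers
   receive 0 and form the *pool* of inactive workers.  Which individuals
   are retained is immaterial — workers are exchangeable and history-free,
   so per-task counts plus the idle count are a sufficient statistic, and
   the whole package operates on counts, never on per-worker agents.
2. **Choice feedback.**  A single per-round distribution over
   `T ∪ {⊥}` is computed from the time-`r` state (option 1: uniform
   `1/|T|`; option 2: uniform on the unsatisfied set `U(r)`; option 3:
   `Φ_i(r)/Φ(r)` on `U(r)`; options 2–3 put all mass on `⊥` when
   `Φ(r) = 0`).  Every pool member draws from it independently, so the
   joint joiner counts are one multinomial draw of the pool size.
3. All transitions apply simultaneously; worker conservation
   `Σ w_i + idle = |A|` holds after every round.

Without noise, per-task deficits never increase, satisfied tasks stay
satisfied, and the inactive pool in round `r+1` always numbers at least
`c·Φ(r)` (it equals `Φ(r) + (c−1)·D`).  Consequently satisfaction is
absorbing and runs stop at the first round with `Φ = 0`.  Under the
informed options the single following round is deterministic (choice
returns `⊥`, so excess workers shed to idle); the simulator executes that
settlement round so the terminal state is a true fixed point.

With choice restricted to unsatisfied tasks (options 2–3), the pool size
`≥ Φ(r)` and the pigeonhole argument guarantee at least one task is
satisfied per round, so every run completes within `|U(0)| ≤ |T|` rounds —
a deterministic fact the test suite asserts with zero tolerance.

## Analytic bounds

All bounds hold for *every* initial configuration, with probability
`1 − δ` over choice randomness only, and are returned as real numbers
(never rounded to integer rounds; a run meets a bound `B` when its
completion round is `≤ B`).

* **Uniform choice (option 1).**  Exact non-asymptotic form
  `K1 · (|T|/c) · (ln Φ(0) + ln(1/δ))` with `K1 = 8`.  The constant is
  frozen by requiring the form to reproduce all published numerical
  evaluations of this bound simultaneously — six full-satisfaction values,
  five approximate-satisfaction values and one sweep intercept, all of
  which it matches to better than 0.01.  The approximate-satisfaction
  variant (residual deficit `≤ ε·Φ(0)`) replaces `ln Φ(0)` by `ln(1/ε)`;
  the two forms coincide at `ε = 1/Φ(0)`.
* **Informed options (2–3).**  Min-forms capped at `|T|`.  Option 2 adds a
  `K2a·(ln Φ(0) + ln(1/δ))` branch and, for `c > 1`, a
  `K2b·(ln |T| + ln(1/δ)) / ln c` branch (which diverges as `c → 1⁺`; the
  min handles the gating, and along a `c`-sweep the curve stays flat at
  its `c = 1` value until roughly `c ≥ e`).  Option 3 adds
  `K3a·(ln Φ(0) + ln(1/δ))` and, for `c > 1`, the same term scaled by
  `K3b/c`.  Published non-asymptotic constants for these options are not
  available, so `K2a, K2b, K3a, K3b` default to 1 and are exposed as
  parameters; the package validates these options primarily through the
  `|T|` cap (exact) and by simulation, not through the log branches.
* **Noisy deficit-weighted bound.**  With choice slack `y` and per-round
  success-flip budget `z`, the guarantee weakens to residual deficit
  `≤ z`.  For `c ≥ 1` the expected deficit contracts to `(3+y)/4` of its
  value per round, so the default branch is
  `K4a · (ln Φ(0) + ln(1/δ)) / ln(4/(3+y))` — the non-asymptotic version
  of a `1/ln(1/y)` rate (the two agree up to constants as `y → 1`, where
  both diverge and the min picks the `|T|` cap; at `y = 0` the form
  reduces to the noise-free logarithmic shape with a fixed rate constant
  rather than collapsing to zero, which is the deliberate design choice
  here).  For `c > 1` the branch is `(K4b/c)·(ln Φ(0) + ln(1/δ))` with no
  `y` dependence: surplus workers cancel the choice slack.

## Noise policies

The admissible perturbations are specified only by bounds (a `(1−y)`
probability floor; at most `z` flipped bits), so concrete seeded policies
are defined to make noisy runs reproducible:

* choice: `uniform_shift` (freed mass spread uniformly over unsatisfied
  tasks — a no-op when deficits are equal) and `random` (seeded Dirichlet
  re-weighting); an explicit target distribution can also be supplied and
  is validated against the floor;
* success bits: `suppress_success` (up to `z` retained workers on the
  highest-deficit tasks are told 0 and rejoin the pool), `fake_success`
  (up to `z` pool members are told 1: excess workers stay on their
  oversubscribed task, idle workers stay idle without redrawing), and
  `random` (uniform sample of bits flipped).  Flips are applied after the
  nominal split and before joiner sampling; the choice distribution is
  computed from the unflipped state, so choice never sees the mistakes.
  The `z` budget is per round, not cumulative.  Flipped 1→0 workers
  receive a choice output and redraw that same round.

The residual-deficit guarantee is checked empirically with
`adversary = suppress_success` (which also perturbs choice within the
floor) at `y ∈ {0.25, 0.5}`, `z ∈ {1, 5}`, `c ∈ {1.0, 1.5}` on a 10-task,
deficit-100 scenario with `δ = 0.1` and 400 runs per combination.

## Exact oracle

Worker exchangeability makes the count process itself Markov: states are
the `C(|A|+|T|, |T|)` compositions of `|A|` into `|T|+1` cells, and the
one-round kernel applies the exact multinomial joiner distribution to the
post-success state (scipy's multinomial pmf; sparse kernel).  Zero-deficit
states are absorbing in the noise-free chain.  Completion-time CDFs and
expected-deficit series come from iterated kernel application.  Instances
above a configurable state cap (default 2×10⁵ states) are rejected with a
size report — exact analysis is for tiny instances only; randomised noise
policies are excluded because the kernel must be a deterministic function
of the state.

Simulator/oracle agreement is tested with the Dvoretzky–Kiefer–Wolfowitz
band `sqrt(ln(2/α)/(2n))` (≈ 0.0163 at `n = 10⁴`, `α = 0.01`) on the
hand-solvable two-worker toy (`P(T≤t) = 1 − 0.5ᵗ` under uniform choice)
and on random tiny instances (`|A| ≤ 6`, `|T| ≤ 3`), plus a negative
control in which deliberately mismatched options must exceed the band.

## Scenario presets and generator

The published insect illustrations specify only `(|T|, c, Φ(0), δ, ε)` per
scenario; the guarantees hold for any configuration with those parameters,
so each preset realises its row with a concrete construction whose derived
parameters match exactly (checked at import):

| preset | demands | `|A|` | initial `w(0)` | `Φ(0)` | `c` | `δ` | `ε` |
|---|---|---|---|---|---|---|---|
| honeybee-predator | (4991, 1×9) | 6500 | all idle | 5000 | 1.3 | 0.05 | 0.3 |
| honeybee-forage | (141, 1×9) | 195 | all idle | 150 | 1.3 | 0.2 | 0.3 |
| rockant-forage | (2, 3, 4, 1) | 17 | (2, 3, 0, 0) | 5 | 1.7 | 0.5 | 0.3 |
| rockant-emigration | (10, 10, 5, 5) | 51 | (5, 0, 0, 0) | 25 | 1.7 | 0.1 | 0.1 |
| bumblebee | (2,2,1,1,1,1,1,1) | 15 | (2,2,1,0,0,0,0,0) | 5 | 1.5 | 0.1 | 0.25 |

Large deficits use a single dominant task (the most adversarial shape for
uniform choice); rows with `Φ(0) < D` pre-satisfy part of the demand so
`c` comes out exactly.  The `(1−δ)` probability level maps to the
inverse-ECDF quantile of the same level (the 0.95 row checks the 95th
percentile, the 0.5 row the median); runs that never complete within the
horizon enter the order statistics as `+∞`.  The worked sample-execution
fixture uses demands (2,4,1,3) with 12 workers and one worker each
initially on tasks 2 and 4, ending at `w = (2,4,1,3)` with 2 idle.

`generate_scenario(n_tasks, total_demand, c_target, skew)` interpolates
demand vectors from equal split (`skew = 0`) to one dominant task
(`skew = 1`), with `|A| = ceil(c_target · D)` and an all-idle start.
Plausible parameter ranges in the modelled regime are `|T|` in 2–20,
deficits of order 5–5000, and `c` in 1–2.

What the generator emulates — and what it does not: demands are static
within a run (re-allocation after one change in conditions), workers are
identical generalists with no switching costs, rounds are exactly
synchronous, and the feedback is exactly the idealised success/choice
pair.  Passing tests therefore speak to the algorithmic content of the
model, not to heterogeneous-worker colonies, fluctuating demand, spatial
structure, or real-time round durations.

## Numerical choices

* Distribution mass is validated to 1 within 1e−9 at construction; kernel
  rows to 1e−12.
* Quantiles are type-1 inverse-ECDF order statistics — completion times
  are small integers and interpolation would be misleading.
* Simulation horizons: the reproduction report uses 50× the ceiling of
  the scenario's analytic bound, so non-termination is conspicuous
  without masking bugs; noise-free runs stop early at zero deficit, so
  the horizon is rarely touched.
* The acceptance script derives every run's seed from the single `--seed`
  argument (run `i` of a block uses `base + i`; blocks are offset so no
  seed is reused across targets).
* Sampling sizes (500–1000 runs per report cell, 10⁴ runs per DKW check,
  1000 fuzzed scenarios in the invariant sweep, 400 runs per noise
  combination) keep statistical resolution comfortably inside each
  check's tolerance while the whole suite runs in well under a minute.

## Known limitations

* The informed-option log-branch constants are defaults, not published
  values; analytic claims for options 2–3 are made only where the `|T|`
  cap binds.
* Worst-case initial configurations are not searched for (which start is
  worst is an open question in this model); presets and the generator
  cover equal-split and maximally skewed extremes instead.
* The exact oracle is limited to instances with at most ~2×10⁵ count
  states; the published insect scenarios are far beyond exact analysis
  and are validated by simulation against the bounds.
* Noise guarantees are validated for the deficit-weighted option only;
  the package permits (but warns on) noisy runs of the other options.
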