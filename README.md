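# colonyalloc

Distributed task allocation in social-insect colonies: a seeded stochastic
simulator, an exact Markov-chain verifier for tiny instances, and analytic
high-probability upper bounds on the time for workers to re-allocate.

## The problem

A colony of `|A|` identical workers must cover a set of tasks `T` (foraging,
brood care, defense, ...), each with an integer demand `d_i` — the number of
worker units needed per round to keep the task satisfied.  A task is
satisfied at time `r` when its worker count `w_i(r) ≥ d_i`; the *deficit* is
`Φ_i(r) = max(0, d_i − w_i(r))` and `Φ(r) = Σ_i Φ_i(r)`.  The colony has at
least as many workers as work, `|A| = c·D` with surplus ratio `c ≥ 1` and
`D = Σ_i d_i`.

Workers act in synchronous rounds using only two local feedback signals:

* **success** — "musical chairs": exactly `min(d_i, w_i)` workers on task
  `i` learn their work was needed; the rest (plus all idle workers) are
  *inactive* and must redraw a task;
* **choice** — a randomly suggested alternative task, under one of three
  distributions that differ in how much demand information workers can
  sense:
  1. uniform over all tasks (no demand information),
  2. uniform over the currently unsatisfied tasks,
  3. deficit-weighted: task `i` with probability `Φ_i(r)/Φ(r)`.

The question is how many rounds the colony needs until every task is
satisfied, starting from a worst-case configuration — and how that time
depends on colony size, the number of tasks, and the surplus ratio `c`
(a candidate explanation for why colonies keep seemingly "inactive"
surplus workers).

## What the package computes

* **`colonyalloc.run` / `replicate`** — seeded executions of the round
  process, completion-round quantiles over replicates, deficit
  trajectories.  Noise variants perturb the deficit-weighted choice
  probabilities within a `(1−y)` multiplicative floor and flip up to `z`
  success bits per round; the achievable guarantee then weakens to a
  residual deficit `≤ z`.
* **`colonyalloc.bounds`** — the analytic bounds.  Uniform choice has the
  exact form `8·(|T|/c)·(ln Φ(0) + ln(1/δ))` (holding with probability
  `1−δ`; the approximate-satisfaction variant replaces `ln Φ(0)` with
  `ln(1/ε)`).  The informed options are min-forms capped at `|T|`: with
  choice restricted to unsatisfied tasks, at least one task is satisfied
  per round (pigeonhole), so `|T|` rounds always suffice.
* **`colonyalloc.oracle`** — exact completion-time CDFs and expected
  deficit series on tiny instances via the absorbing Markov chain on count
  states, used to validate the simulator (Dvoretzky–Kiefer–Wolfowitz band).
* **`colonyalloc.scenarios`** — named insect presets (honey-bee predator
  attack and foraging change, rock-ant foraging and emigration, bumble
  bee), a demand-vector generator, and report/CSV/JSON writers.

## Worked example

The honey-bee predator-attack preset: 10 tasks, 5000 bees to re-allocate to
defense, 6500 bees available (`c = 1.3`), failure probability `δ = 0.05`.

```python
from colonyalloc import ChoiceSpec, bound_option1, get_preset, replicate

preset = get_preset("honeybee-predator")
sc = preset.scenario                      # c = 1.3, D = 5000

b = bound_option1(sc.n_tasks, sc.c, 5000, 0.05)
print(f"analytic uniform-choice bound: {b.rounds:.2f} rounds")

for opt in (1, 3):
    s = replicate(sc, ChoiceSpec(option=opt), n_runs=200, base_seed=42,
                  max_rounds=40_000)
    print(f"option {opt}: median {s.quantile(0.5):.0f}, "
          f"95th pct {s.quantile(0.95):.0f}, max {s.max_round:.0f}")
```

prints

```
analytic uniform-choice bound: 708.49 rounds
option 1: median 14, 95th pct 15, max 15
option 3: median 2, 95th pct 2, max 2
```

The analytic bound guarantees completion within ~708 rounds when bees test
tasks blindly one at a time; the simulation shows typical behaviour is far
faster (≈15 rounds), and that sensing demand directly (option 3) collapses
re-allocation to a couple of rounds — the qualitative gap that makes the
information content of task stimuli the decisive variable.

The same is available from a shell:

```bash
alloc bound --option 1 --tasks 10 --c 1.3 --phi 5000 --delta 0.05
alloc simulate --preset honeybee-predator --option 3 --runs 200 --seed 42
alloc report --runs 1000 --seed 1 --out report.csv
alloc sweep --figure 1 --out curve.csv
alloc oracle --config examples/toy.yaml --option 1 --horizon 10
```

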