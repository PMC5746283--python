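"""Choice-feedback distributions, noise perturbations, and joiner sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonyalloc import (AllocationState, ChoiceDistribution, ChoiceSpec,
                         apply_success_noise, choice_distribution,
                         make_scenario, perturb_choice_distribution,
                         sample_joiners, success_split)


def _state(counts, idle):
    return AllocationState(time=0, counts=np.array(counts), idle=idle)


class TestChoiceSpec:
    def test_noise_requires_adversary(self):
        with pytest.raises(ValueError):
            ChoiceSpec(option=3, y=0.5)
        with pytest.raises(ValueError):
            ChoiceSpec(option=3, adversary="uniform_shift")

    def test_noise_on_uninformed_option_warns(self):
        with pytest.warns(UserWarning):
            ChoiceSpec(option=1, y=0.5, adversary="uniform_shift")

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            ChoiceSpec(option=3, y=1.0, adversary="uniform_shift")
        with pytest.raises(ValueError):
            ChoiceSpec(option=3, z=-1, adversary="suppress_success")


class TestChoiceDistribution:
    def setup_method(self):
        self.sc = make_scenario((2, 4, 1, 3), 12, (0, 1, 0, 1))
        self.state = self.sc.initial_state()

    def test_deficit_weighted(self):
        dist = choice_distribution(self.state, self.sc, ChoiceSpec(option=3))
        assert np.allclose(dist.probabilities, [2 / 8, 3 / 8, 1 / 8, 2 / 8])
        assert dist.bottom == 0.0

    def test_uniform_all(self):
        dist = choice_distribution(self.state, self.sc, ChoiceSpec(option=1))
        assert np.allclose(dist.probabilities, 0.25)

    def test_uniform_unsat_single_task(self):
        state = _state([2, 4, 0, 3], 3)
        dist = choice_distribution(state, self.sc, ChoiceSpec(option=2))
        assert np.allclose(dist.probabilities, [0, 0, 1, 0])

    @pytest.mark.parametrize("option", [2, 3])
    def test_bottom_when_all_satisfied(self, option):
        state = _state([2, 4, 1, 3], 2)
        dist = choice_distribution(state, self.sc, ChoiceSpec(option=option))
        assert dist.bottom == 1.0 and dist.probabilities.sum() == 0.0

    def test_options_1_and_3_coincide_under_equal_deficits(self):
        sc = make_scenario((3, 3, 3), 9, "all-idle")
        d1 = choice_distribution(sc.initial_state(), sc, ChoiceSpec(option=1))
        d3 = choice_distribution(sc.initial_state(), sc, ChoiceSpec(option=3))
        assert np.allclose(d1.full(), d3.full())

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            ChoiceDistribution(np.array([-0.1, 1.1]))


class TestPerturbation:
    def test_zero_noise_is_identity(self):
        dist = ChoiceDistribution(np.array([0.5, 0.5]))
        out = perturb_choice_distribution(dist, 0.0, "uniform_shift")
        assert out is dist

    def test_floor_accepts_boundary_target(self):
        base = ChoiceDistribution(np.array([0.5, 0.5]))
        target = ChoiceDistribution(np.array([0.25, 0.75]))
        out = perturb_choice_distribution(base, 0.5, "uniform_shift",
                                          target=target)
        assert np.allclose(out.probabilities, [0.25, 0.75])

    def test_floor_rejects_violating_target(self):
        base = ChoiceDistribution(np.array([0.5, 0.5]))
        target = ChoiceDistribution(np.array([0.2, 0.8]))
        with pytest.raises(ValueError):
            perturb_choice_distribution(base, 0.5, "uniform_shift",
                                        target=target)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        weights=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
        y=st.floats(0.0, 0.99),
        adversary=st.sampled_from(["uniform_shift", "random"]),
    )
    def test_perturbed_distributions_respect_floor(self, weights, y,
                                                   adversary):
        """Any emitted perturbation keeps each task above (1-y) times its
        nominal mass and remains a probability distribution."""
        probs = np.array(weights) / np.sum(weights)
        base = ChoiceDistribution(probs)
        rng = np.random.default_rng(0)
        out = perturb_choice_distribution(base, y, adversary, rng=rng)
        assert np.all(out.probabilities >= (1 - y) * probs - 1e-12)
        assert abs(out.probabilities.sum() + out.bottom - 1.0) < 1e-9


class TestSuccessNoise:
    def setup_method(self):
        self.sc = make_scenario((1, 1), 2, (2, 0))
        self.state = self.sc.initial_state()
        self.split = success_split(self.state, self.sc)

    def test_zero_budget_is_identity(self):
        out = apply_success_noise(self.split, self.state, self.sc, 0,
                                  "suppress_success")
        assert out is self.split

    def test_suppress_moves_needed_worker_to_pool(self):
        out = apply_success_noise(self.split, self.state, self.sc, 1,
                                  "suppress_success")
        assert list(out.retained) == [0, 0]
        assert out.pool == 2
        assert out.total_workers() == 2

    def test_fake_success_keeps_excess_worker(self):
        out = apply_success_noise(self.split, self.state, self.sc, 1,
                                  "fake_success")
        assert list(out.retained) == [2, 0]  # excess stays oversubscribed
        assert out.pool == 0

    @pytest.mark.parametrize("adversary",
                             ["suppress_success", "fake_success", "random"])
    def test_budget_beyond_colony_conserves_workers(self, adversary):
        sc = make_scenario((2, 3), 8, (4, 1))
        state = sc.initial_state()
        split = success_split(state, sc)
        rng = np.random.default_rng(3)
        out = apply_success_noise(split, state, sc, z=sc.n_workers,
                                  adversary=adversary, rng=rng)
        assert out.total_workers() == sc.n_workers

    def test_idle_flip_locks_idle_worker(self):
        sc = make_scenario((1,), 3, (1,))
        state = sc.initial_state()
        split = success_split(state, sc)
        out = apply_success_noise(split, state, sc, 3, "fake_success")
        assert out.idle_locked == 2 and out.pool == 0


class TestSampleJoiners:
    def test_empty_pool(self):
        dist = ChoiceDistribution(np.array([0.5, 0.5]))
        joiners, idle = sample_joiners(0, dist, np.random.default_rng(0))
        assert list(joiners) == [0, 0] and idle == 0

    def test_degenerate_distribution(self):
        dist = ChoiceDistribution(np.array([0.0, 0.0, 1.0, 0.0]))
        joiners, idle = sample_joiners(10, dist, np.random.default_rng(0))
        assert list(joiners) == [0, 0, 10, 0] and idle == 0

    def test_multinomial_marginals(self):
        """Joiner counts match pool * p_i in expectation (binomial moments:
        each count within 250 +/- 3 sigma, sigma ~ 43, at a fixed seed)."""
        dist = ChoiceDistribution(np.full(4, 0.25))
        rng = np.random.default_rng(12345)
        sigma = np.sqrt(1000 * 0.25 * 0.75)
        draws = np.array([sample_joiners(1000, dist, rng)[0]
                          for _ in range(200)])
        assert np.all(np.abs(draws.mean(axis=0) - 250) < 3 * sigma / np.sqrt(200))
        assert np.all(draws.sum(axis=1) == 1000)

    def test_bottom_mass_goes_idle(self):
        dist = ChoiceDistribution(np.array([0.0]), bottom=1.0)
        joiners, idle = sample_joiners(7, dist, np.random.default_rng(0))
        assert idle == 7 and joiners[0] == 0
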