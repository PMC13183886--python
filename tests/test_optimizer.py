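"""Squirrel-search mechanics and the wrapper fitness objective."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from issoselect import CVMaskEvaluator, exhaustive_search, fitness, run_isso
from issoselect.config import ISSOConfig
from issoselect.errors import StateError, ValidationError
from issoselect.optimizer import (
    FitnessRecord,
    Squirrel,
    assign_roles,
    derive_mask,
    glide_step,
    initialize_population,
    mutate,
    predator_event,
    seasonal_check,
)

from conftest import fast_config


class FakeEvaluator:
    """Deterministic additive fitness: planted bits carry accuracy weight.

    accuracy(mask) = base + sum of per-bit gains for planted bits, minus a
    small clutter penalty per noise bit; lets optimizer mechanics be tested
    without training forests.
    """

    def __init__(self, m=10, planted=(0, 1, 2), gain=0.08, alpha=0.9, beta=0.1):
        self.n_features = m
        self.planted = set(planted)
        self.gain = gain
        self.alpha, self.beta = alpha, beta
        self.n_calls = 0

    def evaluate(self, mask):
        self.n_calls += 1
        mask = np.asarray(mask)
        if mask.sum() == 0:
            raise ValidationError("empty mask")
        acc = 0.5 + self.gain * sum(mask[i] for i in self.planted)
        acc -= 0.005 * sum(
            mask[i] for i in range(self.n_features) if i not in self.planted
        )
        acc = min(max(acc, 0.0), 1.0)
        k = int(mask.sum())
        return FitnessRecord(
            acc, k, self.n_features,
            fitness(acc, k, self.n_features, self.alpha, self.beta),
        )


class TestFitness:
    def test_full_subset_endpoint(self):
        assert fitness(1.0, 13, 13, 0.9, 0.1) == pytest.approx(0.8)

    def test_published_accuracy_and_subset_size(self):
        # 96.4% accuracy with 6 of 13 predictors under alpha/beta = 0.9/0.1
        val = fitness(0.964, 6, 13, 0.9, 0.1)
        assert val == pytest.approx(0.9 * 0.964 - 0.1 * 6 / 13, abs=1e-12)
        assert val == pytest.approx(0.8214461538461539, abs=1e-9)

    def test_single_feature_value(self):
        assert fitness(0.5, 1, 13, 0.9, 0.1) == pytest.approx(0.45 - 0.1 / 13)

    def test_empty_subset_invalid(self):
        with pytest.raises(ValidationError):
            fitness(0.9, 0, 13, 0.9, 0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        acc=st.floats(0, 1),
        m=st.integers(2, 40),
        data=st.data(),
        alpha=st.floats(0, 1),
        beta=st.floats(0.01, 1),
    )
    def test_matches_hand_arithmetic_and_decreases_in_subset_size(
        self, acc, m, data, alpha, beta
    ):
        k = data.draw(st.integers(1, m - 1))
        assert fitness(acc, k, m, alpha, beta) == pytest.approx(
            alpha * acc - beta * (k / m), abs=1e-12
        )
        assert fitness(acc, k, m, alpha, beta) > fitness(acc, k + 1, m, alpha, beta)


class TestMaskRepresentation:
    def test_threshold_derivation_and_repair(self):
        pos = np.array([0.1, 0.2, 0.3])
        mask = derive_mask(pos, 0.5)
        assert mask.sum() == 1 and mask[2] == 1
        assert pos[2] == 0.5  # repaired coordinate lifted to threshold

    def test_population_masks_never_empty(self):
        cfg = ISSOConfig(n_squirrels=30, seed=1)
        pop = initialize_population(13, cfg)
        assert len(pop) == 30
        assert all(s.mask.sum() >= 1 for s in pop)

    def test_single_feature_forces_the_only_bit(self):
        cfg = ISSOConfig(n_squirrels=5, seed=2)
        pop = initialize_population(1, cfg)
        assert all(s.mask.tolist() == [1] for s in pop)

    def test_initialization_deterministic_for_fixed_seed(self):
        cfg = ISSOConfig(n_squirrels=6, seed=7)
        a = initialize_population(9, cfg)
        b = initialize_population(9, cfg)
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.position, t.position)


def _squirrel(fit, k=3, m=10):
    mask = np.zeros(m, dtype=np.int8)
    mask[:k] = 1
    pos = mask.astype(float)
    return Squirrel(pos, mask, FitnessRecord(fit, k, m, fit))


class TestRoles:
    def test_rank_rule_small_population(self):
        pop = [_squirrel(f) for f in (0.9, 0.8, 0.7, 0.6)]
        ranked = assign_roles(pop)
        assert [s.role for s in ranked] == ["hickory", "oak", "normal", "normal"]

    def test_thirty_squirrels_split_1_14_15(self):
        pop = [_squirrel(0.5 + 0.01 * i) for i in range(30)]
        ranked = assign_roles(pop)
        roles = [s.role for s in ranked]
        assert roles.count("hickory") == 1
        assert roles.count("oak") == 14
        assert roles.count("normal") == 15

    def test_tie_breaks_toward_smaller_subset(self):
        pop = [_squirrel(0.7, k=3), _squirrel(0.7, k=2)]
        ranked = assign_roles(pop)
        assert ranked[0].record.n_selected == 2

    def test_unset_fitness_rejected(self):
        s = Squirrel(np.ones(3), np.ones(3, dtype=np.int8))
        with pytest.raises(StateError):
            assign_roles([s])


class TestGlide:
    def test_at_target_is_fixed_point(self):
        cfg = ISSOConfig(n_iterations=10)
        s = _squirrel(0.5)
        t = _squirrel(0.9)
        t.position = s.position.copy()
        out = glide_step(s, t, 0, cfg)
        np.testing.assert_allclose(out.position, s.position)

    def test_unit_step_lands_on_target(self):
        cfg = ISSOConfig(n_iterations=2, dg_max=1.0, dg_min=1.0, glide_constant=1.0)
        s = Squirrel(np.zeros(4), np.zeros(4, dtype=np.int8))
        t = Squirrel(np.ones(4), np.ones(4, dtype=np.int8))
        out = glide_step(s, t, 0, cfg)
        np.testing.assert_allclose(out.position, np.ones(4))

    def test_overshoot_clipped_to_unit_cube(self):
        cfg = ISSOConfig(n_iterations=2, dg_max=2.0, dg_min=2.0, glide_constant=1.0)
        s = Squirrel(np.array([0.2]), np.array([0], dtype=np.int8))
        t = Squirrel(np.array([1.0]), np.array([1], dtype=np.int8))
        out = glide_step(s, t, 0, cfg)
        # raw 0.2 + 2*(0.8) = 1.8 -> clipped
        assert out.position[0] == 1.0

    def test_step_size_decays_linearly(self):
        cfg = ISSOConfig(n_iterations=11, dg_max=1.0, dg_min=0.5, glide_constant=1.0)
        # second coordinate stays above threshold so no repair interferes
        s0 = Squirrel(np.array([0.0, 0.9]), np.array([0, 1], dtype=np.int8))
        t = Squirrel(np.array([0.5, 0.9]), np.array([1, 1], dtype=np.int8))
        early = glide_step(s0, t, 0, cfg).position[0]
        late = glide_step(s0, t, 10, cfg).position[0]
        assert early == pytest.approx(0.5)
        assert late == pytest.approx(0.25)


class TestPredatorAndMutation:
    def test_zero_probability_is_identity(self, rng):
        cfg = ISSOConfig(p_predator=0.0)
        s = _squirrel(0.5)
        s.role = "normal"
        out = predator_event(s, cfg, rng)
        np.testing.assert_array_equal(out.position, s.position)

    def test_certain_predator_relocates_non_hickory(self, rng):
        cfg = ISSOConfig(p_predator=1.0)
        s = _squirrel(0.5)
        s.role = "normal"
        out = predator_event(s, cfg, rng)
        assert not np.array_equal(out.position, s.position)

    def test_hickory_exempt_even_at_certain_probability(self, rng):
        cfg = ISSOConfig(p_predator=1.0)
        s = _squirrel(0.9)
        s.role = "hickory"
        out = predator_event(s, cfg, rng)
        np.testing.assert_array_equal(out.position, s.position)

    def test_relocation_frequency_matches_probability(self, rng):
        cfg = ISSOConfig(p_predator=0.1)
        hits = 0
        trials = 10_000
        s = _squirrel(0.5)
        s.role = "normal"
        for _ in range(trials):
            out = predator_event(s, cfg, rng)
            hits += not np.array_equal(out.position, s.position)
        assert hits / trials == pytest.approx(0.1, abs=0.01)

    def test_mutation_endpoints(self, rng):
        mask = np.array([1, 0, 1, 0], dtype=np.int8)
        np.testing.assert_array_equal(mutate(mask, 0.0, rng), mask)
        np.testing.assert_array_equal(mutate(mask, 1.0, rng), 1 - mask)

    def test_all_ones_complement_repaired(self, rng):
        mask = np.ones(5, dtype=np.int8)
        out = mutate(mask, 1.0, rng)
        assert out.sum() == 1  # complement is all-zero, repair sets one bit

    def test_mean_flip_count_matches_binomial(self, rng):
        mask = np.zeros(13, dtype=np.int8)
        mask[:6] = 1
        flips = []
        for _ in range(10_000):
            out = mutate(mask, 0.01, rng)
            flips.append(int((out != mask).sum()))
        assert np.mean(flips) == pytest.approx(0.13, abs=0.02)


class TestSeasonal:
    def _pop(self, n=30):
        pop = [_squirrel(0.5 + 0.01 * i) for i in range(n)]
        return assign_roles(pop)

    def test_improving_window_leaves_population_alone(self, rng):
        cfg = ISSOConfig(season_interval=10)
        pop = self._pop()
        hist = [0.5] * 10 + [0.6]
        before = [s.position.copy() for s in pop]
        _, relocated = seasonal_check(pop, hist, cfg, rng)
        assert not relocated
        for s, b in zip(pop, before):
            np.testing.assert_array_equal(s.position, b)

    def test_stagnant_window_relocates_worst_half_not_hickory(self, rng):
        cfg = ISSOConfig(season_interval=10)
        pop = self._pop(30)
        hickory_pos = pop[0].position.copy()
        hist = [0.8] * 11  # flat
        _, relocated = seasonal_check(pop, hist, cfg, rng)
        assert relocated
        np.testing.assert_array_equal(pop[0].position, hickory_pos)
        n_reset = sum(s.record is None for s in pop)
        assert n_reset == 15


class TestDrivers:
    def test_history_monotone_and_reproducible(self):
        ev1, ev2 = FakeEvaluator(), FakeEvaluator()
        cfg = ISSOConfig(n_squirrels=10, n_iterations=20, season_interval=5, seed=3)
        m1, r1, h1 = run_isso(ev1, cfg)
        m2, r2, h2 = run_isso(ev2, cfg)
        assert all(a <= b for a, b in zip(h1, h1[1:]))
        np.testing.assert_array_equal(m1, m2)
        assert h1 == h2

    def test_finds_planted_optimum_on_additive_fitness(self):
        ev = FakeEvaluator(m=10, planted=(0, 1, 2))
        cfg = ISSOConfig(n_squirrels=14, n_iterations=30, season_interval=10, seed=1)
        mask, rec, _ = run_isso(ev, cfg)
        assert mask[:3].tolist() == [1, 1, 1]
        assert mask[3:].sum() == 0  # clutter penalty removes noise bits

    def test_zero_iterations_returns_best_initial(self):
        ev = FakeEvaluator()
        cfg = ISSOConfig(n_squirrels=8, n_iterations=0, seed=5)
        mask, rec, hist = run_isso(ev, cfg)
        assert len(hist) == 1
        assert rec.fitness == hist[0]

    def test_exhaustive_enumerates_all_nonempty_masks(self):
        ev = FakeEvaluator(m=3, planted=(0,))
        mask, rec = exhaustive_search(ev)
        assert ev.n_calls == 7
        assert mask.tolist() == [1, 0, 0]

    def test_exhaustive_refuses_large_spaces(self):
        ev = FakeEvaluator(m=16)
        with pytest.raises(ValidationError):
            exhaustive_search(ev)

    def test_exhaustive_dominates_every_mask(self):
        ev = FakeEvaluator(m=6, planted=(1, 4), gain=0.05)
        best_mask, best = exhaustive_search(ev)
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = (rng.random(6) > 0.5).astype(np.int8)
            if mask.sum() == 0:
                mask[0] = 1
            assert ev.evaluate(mask).fitness <= best.fitness + 1e-12


class TestCVEvaluator:
    def test_memoized_repeat_returns_identical_record(self, planted_small):
        proc, _ = planted_small
        ev = CVMaskEvaluator(proc, fast_config(seed=2))
        mask = np.ones(ev.n_features, dtype=np.int8)
        r1 = ev.evaluate(mask)
        unique_before = ev.n_unique_evaluations
        r2 = ev.evaluate(mask)
        assert r1 is r2
        assert ev.n_unique_evaluations == unique_before
        assert ev.n_calls == 2

    def test_separating_feature_alone_scores_high(self):
        from issoselect import Dataset
        from issoselect.dataio import numeric

        rng = np.random.default_rng(12)
        n = 120
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 3))
        X[:, 0] = y * 10.0 + rng.standard_normal(n) * 0.01  # separates perfectly
        ds = Dataset(X, ["a", "b", "c"], [numeric()] * 3, y)
        ev = CVMaskEvaluator(ds, fast_config(seed=4))
        rec = ev.evaluate(np.array([1, 0, 0], dtype=np.int8))
        assert rec.accuracy >= 0.99
        cfg = fast_config().optimizer
        assert rec.fitness == pytest.approx(
            cfg.alpha * rec.accuracy - cfg.beta * (1 / 3), abs=1e-12
        )

    def test_fewer_bits_win_at_equal_accuracy(self):
        # Eq-1 monotonicity carried through the record
        a = fitness(0.9, 2, 8, 0.9, 0.1)
        b = fitness(0.9, 3, 8, 0.9, 0.1)
        assert a > b
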