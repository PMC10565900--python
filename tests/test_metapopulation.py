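import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cheatcycles import (
    DomainError,
    MetaPopParams,
    ModelParams,
    ParameterError,
    PassageParams,
    bottleneck_all,
    fitness_cv,
    grow_all,
    init_metapopulation,
    integerize,
    mix_pairs,
    relative_fitness,
    run_metapopulation,
    run_serial_passage,
)
from cheatcycles.core_model import integrate_growth


class TestInit:
    def test_identical_subpopulations(self):
        subpops = init_metapopulation(3, 5, 5)
        assert subpops.shape == (3, 2)
        assert np.all(subpops == 5.0)

    def test_cooperator_free(self):
        subpops = init_metapopulation(2, 0, 1)
        assert np.all(subpops[:, 0] == 0.0)

    def test_minimum_size(self):
        with pytest.raises(ParameterError):
            init_metapopulation(1, 5, 5)


class TestIntegerize:
    def test_round_half_away_from_zero(self):
        assert integerize(4.6) == 5.0
        assert integerize(4.5) == 5.0
        assert integerize(0.4) == 0.0

    def test_integer_input_unchanged(self):
        assert integerize(7.0) == 7.0

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            integerize(-0.1)

    def test_stochastic_rounding_bracket(self, rng):
        vals = np.array([integerize(2.3, "stochastic", rng) for _ in range(200)])
        assert set(np.unique(vals)) <= {2.0, 3.0}
        assert abs(vals.mean() - 2.3) < 0.15  # unbiased in expectation

    def test_none_mode_identity(self):
        x = np.array([1.2, 3.7])
        assert np.array_equal(integerize(x, "none"), x)

    @given(st.floats(0.0, 1e6, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_on_integers(self, x):
        once = integerize(x)
        assert integerize(once) == once


class TestGrowAll:
    def test_identical_inputs_identical_outputs(self, model):
        subpops = init_metapopulation(4, 1, 1)
        grown = grow_all(subpops, model, 5.0)
        assert np.all(grown == grown[0])

    def test_empty_subpop_stays_empty(self, model):
        grown = grow_all(np.array([[0.0, 0.0], [1.0, 1.0]]), model, 5.0)
        assert np.array_equal(grown[0], [0.0, 0.0])

    def test_matches_single_integration(self, model):
        grown = grow_all(np.array([[1.0, 2.0]]), model, 7.0)
        end = integrate_growth((1.0, 2.0), model, 7.0, end_state_only=True)
        assert grown[0, 0] == pytest.approx(end.n_co, abs=1e-8)
        assert grown[0, 1] == pytest.approx(end.n_ch, abs=1e-8)

    def test_cache_reuse_is_exact(self, model):
        cache = {}
        a = grow_all(np.array([[2.0, 3.0]]), model, 5.0, cache=cache)
        b = grow_all(np.array([[2.0, 3.0], [2.0, 3.0]]), model, 5.0, cache=cache)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[0], b[1])


class TestMixPairs:
    def test_zero_events_unchanged(self, rng):
        subpops = np.array([[3.0, 4.0], [5.0, 6.0]])
        out = mix_pairs(subpops, 0.0, rng)
        assert np.array_equal(out, subpops)

    def test_identical_pool_unchanged_round_mode(self, rng):
        subpops = np.array([[4.0, 6.0], [4.0, 6.0]])
        out = mix_pairs(subpops, 10.0, rng, integer_mode="round")
        assert np.array_equal(out, subpops)

    def test_round_mode_conserves_within_one_per_strain(self, rng):
        # one event: pooled total 2n or 2n+1 -> two copies of round half
        for pair in ([3.0, 0.0], [4.0, 1.0]), ([2.0, 7.0], [5.0, 2.0]):
            subpops = np.array(pair)
            out = mix_pairs(subpops, 0.5, rng, integer_mode="round")  # 1 event
            for strain in range(2):
                total_in = subpops[:, strain].sum()
                total_out = out[:, strain].sum()
                assert abs(total_out - total_in) <= 1.0

    def test_binomial_mode_conserves_exactly(self, rng):
        subpops = np.array([[3.0, 9.0], [8.0, 2.0], [1.0, 5.0]])
        out = mix_pairs(subpops, 4.0, rng, integer_mode="binomial")
        assert np.array_equal(out.sum(axis=0), subpops.sum(axis=0))
        assert np.all(out >= 0)
        assert np.all(out == np.floor(out))

    def test_binomial_split_unbiased(self):
        # expected pooled share of each new subpopulation is half the pool
        firsts = []
        for seed in range(400):
            r = np.random.default_rng(seed)
            out = mix_pairs(np.array([[10.0, 0.0], [10.0, 0.0]]), 0.5, r, "binomial")
            firsts.append(out[0, 0])
        assert abs(np.mean(firsts) - 10.0) < 0.5


class TestBottleneck:
    def test_plain_division(self):
        out = bottleneck_all(np.array([[100.0, 50.0]]), 10.0, "round")
        assert np.array_equal(out, [[10.0, 5.0]])

    def test_rounding_extinction(self):
        out = bottleneck_all(np.array([[4.0, 4.0]]), 10.0, "round")
        assert np.array_equal(out, [[0.0, 0.0]])

    def test_identity_dilution_is_integerization(self):
        out = bottleneck_all(np.array([[3.4, 5.6]]), 1.0, "round")
        assert np.array_equal(out, [[3.0, 6.0]])

    def test_invalid_ratio(self):
        with pytest.raises(ParameterError):
            bottleneck_all(np.array([[1.0, 1.0]]), 0.5)

    def test_binomial_thinning_statistics(self):
        draws = [
            bottleneck_all(
                np.array([[1000.0, 0.0]]), 10.0, "binomial", np.random.default_rng(s)
            )[0, 0]
            for s in range(200)
        ]
        assert abs(np.mean(draws) - 100.0) < 3.0
        assert np.std(draws) > 0  # genuinely stochastic


class TestRelativeFitness:
    def test_equal_fold_change_is_one(self):
        assert relative_fitness((10, 10), (50, 50)) == pytest.approx(1.0)

    def test_log_ratio_arithmetic(self):
        # co 10->100 (x10), ch 10->1000 (x100): ln(100)/ln(10) = 2
        assert relative_fitness((10, 10), (100, 1000)) == pytest.approx(2.0)

    def test_extinct_strain_undefined(self):
        assert np.isnan(relative_fitness((10, 10), (100, 0)))

    def test_zero_cooperator_change_undefined(self):
        assert np.isnan(relative_fitness((10, 10), (10, 20)))


class TestFitnessCV:
    def test_equal_values_zero(self):
        assert fitness_cv([1.3, 1.3, 1.3]) == 0.0

    def test_two_values(self):
        # sd({1,3}, ddof=1) = sqrt(2), mean = 2
        assert fitness_cv([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)

    def test_scale_invariance(self, rng):
        vals = rng.uniform(0.5, 2.0, size=20)
        assert fitness_cv(vals * 7.3) == pytest.approx(fitness_cv(vals))

    def test_single_defined_value_undefined(self):
        assert np.isnan(fitness_cv([1.0, np.nan]))


class TestRunMetapopulation:
    def test_seeded_determinism(self, model):
        meta = MetaPopParams(M=10, K_sub=50.0, n_cycles=10, burn_in_cycles=2, seed=7)
        r1 = run_metapopulation(model, meta)
        r2 = run_metapopulation(model, meta)
        assert np.array_equal(r1.global_p_cheat, r2.global_p_cheat)
        assert np.array_equal(r1.fitness, r2.fitness, equal_nan=True)
        assert np.array_equal(r1.final_subpops, r2.final_subpops)

    def test_different_seeds_diverge(self, model):
        meta = lambda s: MetaPopParams(
            M=10, K_sub=50.0, n_cycles=10, burn_in_cycles=2, seed=s
        )
        r1 = run_metapopulation(model, meta(1))
        r2 = run_metapopulation(model, meta(2))
        assert not np.array_equal(r1.global_p_cheat, r2.global_p_cheat)

    def test_counts_are_non_negative_integers(self, model):
        meta = MetaPopParams(M=8, K_sub=50.0, n_cycles=5, burn_in_cycles=1, seed=3)
        rec = run_metapopulation(model, meta)
        assert np.all(rec.final_subpops >= 0)
        assert np.array_equal(rec.final_subpops, np.floor(rec.final_subpops))

    def test_deterministic_limit_matches_serial_passage(self, coarse_solver):
        # integerization and mixing off: every subpopulation is the scenario-2 map
        model = ModelParams(a=1.0, b=0.0)
        meta = MetaPopParams(
            M=3, K_sub=None, F=0.0, D=10.0, n_cycles=20, burn_in_cycles=5,
            n0_co=1, n0_ch=1, integer_mode="none",
        )
        rec = run_metapopulation(model, meta, coarse_solver)
        passage = PassageParams(D=10.0, tgrow=10.0, n_cycles=20, burn_in_cycles=5)
        records = run_serial_passage(model, passage, (1.0, 1.0), coarse_solver)
        expected = np.array([r.end_p_cheat for r in records])
        assert np.allclose(rec.global_p_cheat, expected, atol=1e-6)

    def test_global_extinction_terminates_early(self):
        model = ModelParams(a=0.0, b=0.0, h=1.0, r=0.01)
        meta = MetaPopParams(
            M=4, K_sub=None, F=0.0, D=10.0, tgrow=0.1,
            n_cycles=30, burn_in_cycles=0, n0_co=1, n0_ch=1, seed=0,
        )
        rec = run_metapopulation(model, meta)
        assert rec.extinct_cycle is not None
        assert rec.n_cycles_run == rec.extinct_cycle + 1

    def test_capacity_rescaling_applied(self, model):
        meta = MetaPopParams(M=6, K_sub=50.0, n_cycles=4, burn_in_cycles=0, seed=5)
        rec = run_metapopulation(model, meta)
        # populations grow toward K_sub, far above the unscaled K = 10
        assert rec.final_subpops.sum(axis=1).max() > 2.0  # post-dilution ~K_sub/D
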