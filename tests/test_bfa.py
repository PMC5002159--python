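"""Binary firefly operators and the main optimization loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bfadbp import (
    BFAConfig,
    alpha_schedule,
    attract,
    attractiveness,
    bits_from_string,
    mutate,
    optimize,
    similarity,
)
from bfadbp.bfa import ContractError, move_firefly

bitstrings = st.lists(st.integers(0, 1), min_size=1, max_size=64).map(np.array)


class TestSimilarity:
    def test_worked_example(self):
        # 3 of 10 bits differ -> r = 1 - 3/10
        assert similarity(
            bits_from_string("1001111000"), bits_from_string("1011011100")
        ) == pytest.approx(0.7)

    def test_identical_strings(self):
        x = bits_from_string("10101")
        assert similarity(x, x) == 1.0

    def test_complement_strings(self):
        x = bits_from_string("10101")
        assert similarity(x, 1 - x) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            similarity(bits_from_string("10"), bits_from_string("101"))

    @given(a=bitstrings, b=bitstrings, c=bitstrings)
    @settings(max_examples=100, derandomize=True)
    def test_symmetry_and_triangle_inequality(self, a, b, c):
        n = min(a.size, b.size, c.size)
        a, b, c = a[:n], b[:n], c[:n]
        assert similarity(a, b) == similarity(b, a)
        # 1 - r is the normalized Hamming distance, a metric
        d = lambda x, y: 1.0 - similarity(x, y)
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-12


class TestAttractiveness:
    def test_zero_distance_gives_beta0(self):
        assert attractiveness(0.0, BFAConfig(beta0=0.8)) == pytest.approx(0.8)

    def test_hand_evaluated_point(self):
        cfg = BFAConfig(beta0=1.0, gamma_fa=1.0)
        assert attractiveness(0.7, cfg) == pytest.approx(np.exp(-0.49))
        assert attractiveness(0.7, cfg) == pytest.approx(0.61263, abs=1e-5)

    def test_zero_absorption_is_constant(self):
        cfg = BFAConfig(gamma_fa=0.0, beta0=0.9)
        for r in (0.0, 0.3, 1.0):
            assert attractiveness(r, cfg) == pytest.approx(0.9)


class TestAttractMutate:
    def test_beta_one_copies_brighter(self, rng):
        mover = rng.integers(0, 2, 40).astype(np.uint8)
        brighter = rng.integers(0, 2, 40).astype(np.uint8)
        np.testing.assert_array_equal(attract(mover, brighter, 1.0, rng), brighter)

    def test_beta_zero_is_identity(self, rng):
        mover = rng.integers(0, 2, 40).astype(np.uint8)
        brighter = rng.integers(0, 2, 40).astype(np.uint8)
        np.testing.assert_array_equal(attract(mover, brighter, 0.0, rng), mover)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=50, derandomize=True)
    def test_agreeing_bits_never_change_and_distance_shrinks(self, seed):
        rng = np.random.default_rng(seed)
        mover = rng.integers(0, 2, 30).astype(np.uint8)
        brighter = rng.integers(0, 2, 30).astype(np.uint8)
        moved = attract(mover, brighter, 0.5, rng)
        agree = mover == brighter
        assert np.array_equal(moved[agree], mover[agree])
        assert np.count_nonzero(moved != brighter) <= np.count_nonzero(
            mover != brighter
        )

    def test_mutate_alpha_zero_is_identity(self, rng):
        bits = rng.integers(0, 2, 40).astype(np.uint8)
        np.testing.assert_array_equal(mutate(bits, 0.0, rng), bits)

    def test_mutate_alpha_one_is_complement(self, rng):
        bits = rng.integers(0, 2, 40).astype(np.uint8)
        np.testing.assert_array_equal(mutate(bits, 1.0, rng), 1 - bits)


class TestAlphaSchedule:
    def test_endpoints_and_midpoint(self):
        assert alpha_schedule(0, 500) == 0.5
        assert alpha_schedule(500, 500) == 0.0
        assert alpha_schedule(250, 500) == 0.25

    def test_out_of_range_is_contract_error(self):
        with pytest.raises(ContractError):
            alpha_schedule(501, 500)
        with pytest.raises(ContractError):
            alpha_schedule(-1, 500)


class TestMoveFirefly:
    def test_sweep_equals_operator_composition(self, rng):
        """The fast sweep is the exact attract∘mutate composition."""
        cfg = BFAConfig()
        n = 25
        x = rng.integers(0, 2, n).astype(np.uint8)
        brighter = [rng.integers(0, 2, n).astype(np.uint8) for _ in range(5)]
        randoms = rng.random((5, 2, n))

        class Replay:
            def __init__(self, rows):
                self.rows = list(rows)

            def random(self, size):
                return self.rows.pop(0)

        fast = move_firefly(x.copy(), brighter, 0.3, cfg, randoms)
        replay = Replay([randoms[k, i] for k in range(5) for i in (0, 1)])
        slow = x.copy()
        for xj in brighter:
            beta = attractiveness(similarity(slow, xj), cfg)
            slow = attract(slow, xj, beta, replay)
            slow = mutate(slow, 0.3, replay)
        np.testing.assert_array_equal(fast, slow)


class TestOptimize:
    def test_onemax_reaches_global_optimum(self):
        cfg = BFAConfig(max_iterations=200, rng_seed=42)
        result = optimize(lambda bits: float(bits.sum()), 12, cfg)
        assert result.best_brightness == 12.0
        assert result.best_bits.sum() == 12

    def test_constant_objective_terminates_with_flat_trace(self):
        cfg = BFAConfig(population_size=5, max_iterations=20, rng_seed=0)
        result = optimize(lambda bits: 1.0, 8, cfg)
        assert result.trace == [1.0] * 20

    def test_trace_monotone_under_elitism(self):
        cfg = BFAConfig(population_size=8, max_iterations=60, rng_seed=5)
        result = optimize(lambda bits: float(bits.sum()), 16, cfg)
        assert all(a <= b for a, b in zip(result.trace, result.trace[1:]))

    def test_bit_reproducible(self):
        cfg = BFAConfig(population_size=6, max_iterations=30, rng_seed=9)
        obj = lambda bits: float((bits * np.arange(1, 11)).sum())
        first = optimize(obj, 10, cfg)
        second = optimize(obj, 10, cfg)
        np.testing.assert_array_equal(first.best_bits, second.best_bits)
        assert first.trace == second.trace

    def test_objective_error_carries_context(self):
        def broken(bits):
            raise ValueError("boom")

        with pytest.raises(RuntimeError, match="objective failed"):
            optimize(broken, 4, BFAConfig(population_size=2, max_iterations=2))

    def test_defaults_match_reference_protocol(self):
        cfg = BFAConfig()
        assert (cfg.population_size, cfg.max_iterations, cfg.gamma_fa) == (30, 500, 1.0)
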