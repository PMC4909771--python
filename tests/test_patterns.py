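"""Pattern generation, Willshaw / zip-net storage, retrieval, output noise."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from synaptica.patterns import (ParameterError, PatternSet, generate_patterns,
                                output_noise, p1_expected, retrieve,
                                store_willshaw, store_zipnet)


class TestGeneratePatterns:
    def test_saturated_fixed_size_is_all_ones(self):
        ps = generate_patterns(4, 4, 4, 4, 1, mode="fixed-size", seed=0)
        assert list(ps.u[0]) == [0, 1, 2, 3]
        assert list(ps.v[0]) == [0, 1, 2, 3]

    def test_empty_set_stores_to_zero_matrix(self):
        ps = generate_patterns(5, 6, 2, 2, 0, seed=0)
        assert ps.M == 0
        assert store_willshaw(ps).W.sum() == 0

    def test_bernoulli_mean_activity(self):
        # mean |u| over M=20 patterns ~ Binomial(1000, 0.05): 50 +- 3 SE
        ps = generate_patterns(1000, 1000, 50, 50, 20, mode="bernoulli", seed=1)
        mean_u = np.mean([len(a) for a in ps.u])
        se = np.sqrt(50 * 0.95) / np.sqrt(20)
        assert abs(mean_u - 50) < 3 * se

    def test_fixed_size_is_exact(self):
        ps = generate_patterns(100, 200, 7, 11, 5, mode="fixed-size", seed=3)
        assert all(len(a) == 7 for a in ps.u)
        assert all(len(a) == 11 for a in ps.v)

    def test_deterministic_given_seed(self):
        a = generate_patterns(50, 50, 5, 5, 4, seed=9)
        b = generate_patterns(50, 50, 5, 5, 4, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a.u, b.u))

    @pytest.mark.parametrize("bad", [dict(k=0), dict(l=0), dict(k=11), dict(M=-1)])
    def test_invalid_sizes_rejected(self, bad):
        kw = dict(m=10, n=10, k=2, l=2, M=1)
        kw.update(bad)
        with pytest.raises(ParameterError):
            generate_patterns(**kw)


class TestStoreWillshaw:
    def test_hand_example(self, tiny_patterns):
        W = store_willshaw(tiny_patterns).W
        expected = np.zeros((4, 4), dtype=np.uint8)
        expected[[0, 0, 1, 1], [0, 2, 0, 2]] = 1
        np.testing.assert_array_equal(W, expected)

    def test_zero_mask_clears_everything(self, tiny_patterns):
        W = store_willshaw(tiny_patterns, mask=np.zeros((4, 4), dtype=np.uint8))
        assert W.W.sum() == 0

    def test_storing_superset_never_clears_weights(self, rng):
        ps1 = generate_patterns(30, 30, 4, 4, 5, seed=11)
        ps2 = generate_patterns(30, 30, 4, 4, 3, seed=12)
        both = PatternSet(m=30, n=30, u=ps1.u + ps2.u, v=ps1.v + ps2.v, k=4, l=4)
        W1 = store_willshaw(ps1).W
        W12 = store_willshaw(both).W
        assert np.all(W1 <= W12)

    def test_empirical_p1_matches_expectation(self):
        # weight entries are correlated within co-activation blocks, so the
        # SE comes from independent replicate memory sets
        m = n = 200
        k = l = 10
        M = 25
        rng = np.random.default_rng(21)
        fracs = []
        for _ in range(30):
            ps = generate_patterns(m, n, k, l, M, mode="bernoulli", seed=rng)
            fracs.append(store_willshaw(ps).W.mean())
        p1 = p1_expected(k, l, m, n, M)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - p1) < 3 * se


class TestStoreZipnet:
    def test_full_quota_realizes_every_potential_synapse(self, rng):
        ps = generate_patterns(20, 20, 4, 4, 5, seed=2)
        pot = (rng.random((20, 20)) < 0.5).astype(np.uint8)
        P_pot = pot.mean()
        W = store_zipnet(ps, pot, target_P1=P_pot)
        np.testing.assert_array_equal(W.W, pot)

    def test_empty_set_tie_break_count(self, rng):
        # all potentials zero: exactly ceil(frac * n_pot_j) ones per column
        ps = PatternSet(m=12, n=10, u=[], v=[], k=3, l=3)
        pot = (rng.random((12, 10)) < 0.7).astype(np.uint8)
        frac = 0.35 / pot.mean()
        W = store_zipnet(ps, pot, target_P1=0.35)
        for j in range(10):
            npot = pot[:, j].sum()
            assert W.W[:, j].sum() == int(np.ceil(frac * npot))

    def test_realized_fraction_matches_target(self, rng):
        ps = generate_patterns(20, 20, 4, 4, 5, seed=5)
        pot = (rng.random((20, 20)) < 0.8).astype(np.uint8)
        W = store_zipnet(ps, pot, target_P1=0.4)
        frac = W.W.sum() / pot.sum()
        # per-column quantization error at most 1/(#potential per column)
        assert abs(frac - 0.4 / pot.mean()) < 1.0 / min(pot.sum(axis=0))

    def test_infeasible_target_raises(self, rng):
        ps = generate_patterns(10, 10, 2, 2, 1, seed=0)
        pot = (rng.random((10, 10)) < 0.3).astype(np.uint8)
        with pytest.raises(ParameterError):
            store_zipnet(ps, pot, target_P1=0.9)


class TestRetrieve:
    def test_pattern_part_recovers_stored_memory(self, tiny_patterns):
        W = store_willshaw(tiny_patterns)
        query = np.array([1, 1, 0, 0], dtype=np.uint8)
        res = retrieve(W, query, strategy="pattern-part")
        assert set(res.active()) == {0, 2}

    def test_zero_weights_fixed_theta_gives_silence(self):
        from synaptica.patterns import WeightMatrix
        W = WeightMatrix(W=np.zeros((4, 4), dtype=np.uint8),
                         mask=np.ones((4, 4), dtype=np.uint8))
        res = retrieve(W, np.array([1, 1, 0, 0]), strategy="fixed-theta", theta=1)
        assert res.v_hat.sum() == 0

    def test_empty_query_l_winner_returns_empty_with_warning(self, tiny_patterns):
        W = store_willshaw(tiny_patterns)
        with pytest.warns(UserWarning):
            res = retrieve(W, np.zeros(4, dtype=np.uint8), strategy="l-winner", l=2)
        assert res.warning and res.v_hat.sum() == 0

    def test_l_winner_activates_at_least_l(self, rng):
        ps = generate_patterns(50, 50, 6, 6, 8, seed=4)
        W = store_willshaw(ps)
        query = np.zeros(50, dtype=np.uint8)
        query[ps.u[0]] = 1
        res = retrieve(W, query, strategy="l-winner", l=6)
        assert res.v_hat.sum() >= 6

    def test_noise_is_deterministic_given_seed(self, tiny_patterns):
        W = store_willshaw(tiny_patterns)
        q = np.array([1, 1, 0, 0], dtype=np.uint8)
        r1 = retrieve(W, q, strategy="fixed-theta", theta=1, noise_max=2.0, seed=7)
        r2 = retrieve(W, q, strategy="fixed-theta", theta=1, noise_max=2.0, seed=7)
        np.testing.assert_array_equal(r1.noise_draws, r2.noise_draws)

    @given(st.integers(0, 2**31 - 1))
    def test_pattern_part_has_zero_miss_errors_on_any_mask(self, seed):
        rng = np.random.default_rng(seed)
        ps = generate_patterns(30, 30, 4, 4, 6, seed=rng)
        mask = (rng.random((30, 30)) < rng.uniform(0.2, 1.0)).astype(np.uint8)
        W = store_willshaw(ps, mask)
        mu = int(rng.integers(6))
        query = np.zeros(30, dtype=np.uint8)
        query[ps.u[mu]] = 1
        res = retrieve(W, query, strategy="pattern-part")
        v_true = np.zeros(30, dtype=bool)
        v_true[ps.v[mu]] = True
        _, _, misses = output_noise(res.v_hat, v_true, 4)
        assert misses == 0


class TestOutputNoise:
    def test_perfect_recall_is_zero(self):
        v = np.array([1, 0, 1, 0])
        assert output_noise(v, v, 2) == (0.0, 0, 0)

    def test_one_miss_one_add(self):
        v_true = np.array([1, 1, 1, 0, 0, 0])
        v_hat = np.array([1, 1, 0, 1, 0, 0])
        eps, adds, misses = output_noise(v_hat, v_true, 3)
        assert (eps, adds, misses) == (2 / 3, 1, 1)

    def test_complement_counts_all_units(self):
        v_true = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        eps, _, _ = output_noise(1 - v_true, v_true, 3)
        assert eps == pytest.approx(8 / 3)

    def test_zero_l_rejected(self):
        with pytest.raises(ParameterError):
            output_noise(np.array([1]), np.array([1]), 0)


class TestP1Expected:
    def test_no_memories(self):
        assert p1_expected(50, 50, 1000, 1000, 0) == 0.0

    def test_printed_consolidation_load(self):
        assert p1_expected(50, 50, 1000, 1000, 20) == pytest.approx(0.04883012474683423, rel=1e-12)

    def test_log_space_large_M(self):
        # high-precision reference: 1 - (1 - 2.5e-7)^800000
        assert p1_expected(50, 50, 100000, 100000, 800000) == pytest.approx(
            0.18126926739029012, rel=1e-12)

    def test_single_pattern(self):
        assert p1_expected(3, 4, 10, 20, 1) == pytest.approx(12 / 200)
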