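"""Cyclic shifts, delay estimation, shift-invariant rank-1 updates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shiftcpd.shift_invariant import (
    cyclic_shift,
    delay_candidates,
    estimate_delay,
    estimate_delays,
    shift_rank1_update,
)

from conftest import crandn


def brute_delay(m, b, c, max_delay):
    """Independent time-domain oracle with explicit loops and the same
    tie-break (smallest |tau| first, negative before positive)."""
    J = len(b)
    best_tau, best_score = None, -np.inf
    order = [0]
    for d in range(1, max_delay + 1):
        order += [-d, d]
    seen = set()
    for t in order:
        if t % J in seen:
            continue
        seen.add(t % J)
        score = 0.0
        for j in range(J):
            score += (np.conj(m[j]) * c * b[(j + t) % J]).real
        if score > best_score:
            best_score, best_tau = score, t
    return best_tau


class TestCyclicShift:
    def test_zero_and_full_cycle_identity(self, rng):
        b = crandn(rng, (9,))
        assert np.array_equal(cyclic_shift(b, 0), b)
        assert np.array_equal(cyclic_shift(b, 9), b)

    def test_left_shift_convention(self):
        b = np.arange(5.0)
        # element j of the output is b[(j + tau) mod J] for tau > 0
        assert np.array_equal(cyclic_shift(b, 2), np.array([2.0, 3, 4, 0, 1]))

    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 2**16),
        a=st.integers(-12, 12),
        c=st.integers(-12, 12),
        J=st.integers(1, 16),
    )
    def test_shifts_compose_additively(self, seed, a, c, J):
        b = crandn(np.random.default_rng(seed), (J,))
        assert np.array_equal(
            cyclic_shift(cyclic_shift(b, a), c), cyclic_shift(b, a + c)
        )

    def test_unitarity(self, rng):
        x = crandn(rng, (11,))
        y = crandn(rng, (11,))
        for tau in (-4, 0, 3):
            assert np.isclose(
                np.vdot(cyclic_shift(x, tau), cyclic_shift(y, tau)), np.vdot(x, y)
            )
            assert np.isclose(
                np.linalg.norm(cyclic_shift(x, tau)), np.linalg.norm(x)
            )


class TestEstimateDelay:
    def test_unshifted_gives_zero(self, rng):
        b = crandn(rng, (32,))
        c = 0.8 - 0.3j
        assert estimate_delay(c * b, b, c, 10) == 0

    @pytest.mark.parametrize("tau0", [-10, -3, 0, 4, 10])
    def test_planted_shift_recovered(self, rng, tau0):
        b = crandn(rng, (64,))
        c = 1.1 + 0.4j
        m = c * cyclic_shift(b, tau0)
        assert estimate_delay(m, b, c, 10) == tau0
        assert estimate_delay(m, b, c, 10, method="exhaustive") == tau0

    @pytest.mark.parametrize("J", [2, 3, 5, 8, 16, 33, 64])
    def test_fft_equals_exhaustive_and_brute_small_J(self, J):
        rng = np.random.default_rng(J)
        for trial in range(15):
            m = crandn(rng, (J,))
            b = crandn(rng, (J,))
            c = complex(*rng.standard_normal(2))
            max_d = min(10, J)
            t_fft = estimate_delay(m, b, c, max_d, method="fft")
            t_ex = estimate_delay(m, b, c, max_d, method="exhaustive")
            assert t_fft == t_ex == brute_delay(m, b, c, max_d)

    def test_fft_equals_exhaustive_at_J160(self):
        rng = np.random.default_rng(160)
        for trial in range(20):
            m = crandn(rng, (160,))
            b = crandn(rng, (160,))
            c = complex(*rng.standard_normal(2))
            assert estimate_delay(m, b, c, 10) == estimate_delay(
                m, b, c, 10, method="exhaustive"
            )

    def test_vectorized_equals_scalar(self, rng):
        J, K = 40, 6
        Mr = crandn(rng, (J, K))
        b = crandn(rng, (J,))
        c = crandn(rng, (K,))
        taus = estimate_delays(Mr, b, c, 10)
        for k in range(K):
            assert taus[k] == estimate_delay(Mr[:, k], b, c[k], 10)

    def test_tie_break_prefers_small_then_negative(self):
        # constant b: every shift scores identically -> tau = 0 wins
        b = np.ones(12, dtype=complex)
        m = np.ones(12, dtype=complex)
        assert estimate_delay(m, b, 1.0 + 0j, 5) == 0
        cands = delay_candidates(12, 3)
        assert cands.tolist() == [0, -1, 1, -2, 2, -3, 3]


class TestShiftRank1Update:
    def test_fixed_point_on_consistent_model(self, rng):
        J, K = 40, 6
        b = crandn(rng, (J,))
        b /= np.linalg.norm(b)
        c = crandn(rng, (K,))
        c /= np.linalg.norm(c)
        tau = rng.integers(-8, 9, K)
        Mr = np.stack(
            [cyclic_shift(b, int(t)) * ci for t, ci in zip(tau, c)], axis=1
        )
        b2, c2 = shift_rank1_update(Mr, b, c, tau)
        assert abs(abs(np.vdot(b2, b)) - 1) < 1e-10
        assert abs(abs(np.vdot(c2, c)) - 1) < 1e-10
        # residual of the refit model (scale recovered via LS) is ~0
        alpha = sum(
            np.vdot(cyclic_shift(b2, int(tau[k])) * c2[k], Mr[:, k]).conj()
            for k in range(K)
        )
        Mr2 = np.stack(
            [cyclic_shift(b2, int(t)) * ci for t, ci in zip(tau, c2)], axis=1
        ) * alpha
        assert np.linalg.norm(Mr - Mr2) < 1e-10

    def test_zero_delays_reduce_to_rank1_ls(self, rng):
        from shiftcpd.arr_r1ls import rank1_ls

        J, K = 24, 5
        Mr = crandn(rng, (J, K))
        b0 = crandn(rng, (J,))
        c0 = crandn(rng, (K,))
        b_s, c_s = shift_rank1_update(Mr, b0, c0, np.zeros(K, dtype=int))
        b_p, c_p = rank1_ls(Mr, b0, c0)
        assert np.allclose(b_s, b_p / np.linalg.norm(b_p))
        # the unconstrained c refit differs only by the normalizations
        c_ref = Mr.T @ np.conj(b_s)
        assert np.allclose(c_s, c_ref / np.linalg.norm(c_ref))

    def test_output_norms_are_one(self, rng):
        Mr = crandn(rng, (16, 4))
        b, c = shift_rank1_update(
            Mr, crandn(rng, (16,)), crandn(rng, (4,)), np.array([0, 1, -2, 3])
        )
        assert np.isclose(np.linalg.norm(b), 1.0)
        assert np.isclose(np.linalg.norm(c), 1.0)

    def test_residual_non_increasing_before_c_normalization(self, rng):
        J, K = 32, 5
        b = crandn(rng, (J,))
        b /= np.linalg.norm(b)
        c = crandn(rng, (K,))
        tau = rng.integers(-5, 6, K)
        Mr = np.stack(
            [cyclic_shift(b, int(t)) * ci for t, ci in zip(tau, c)], axis=1
        )
        Mr += 0.4 * crandn(rng, (J, K))

        def resid(bb, cc):
            return sum(
                np.linalg.norm(Mr[:, k] - cyclic_shift(bb, int(tau[k])) * cc[k]) ** 2
                for k in range(K)
            )

        r0 = resid(b, c)
        b2, _ = shift_rank1_update(Mr, b, c, tau)
        c_raw = np.array(
            [np.vdot(cyclic_shift(b2, int(tau[k])), Mr[:, k]) for k in range(K)]
        )
        assert resid(b2, c_raw) <= r0 + 1e-10

    def test_noisy_delay_recovery_at_0db(self):
        # planted shifted-rank-1 data with complex Gaussian noise at 0 dB
        rng = np.random.default_rng(77)
        J, K = 80, 10
        b = crandn(rng, (J,))
        b /= np.linalg.norm(b)
        c = 0.5 + rng.random(K) + 0j
        tau_true = rng.integers(-5, 6, K)
        Mr = np.stack(
            [cyclic_shift(b, int(t)) * ci for t, ci in zip(tau_true, c)], axis=1
        )
        sig = np.std(Mr)
        Mr_noisy = Mr + crandn(rng, (J, K)) * sig / np.sqrt(2)
        b_e = b + 0.05 * crandn(rng, (J,))
        c_e = c.astype(complex)
        tau = np.zeros(K, dtype=int)
        for _ in range(10):
            tau = estimate_delays(Mr_noisy, b_e, c_e, 10)
            b_e, c_e = shift_rank1_update(Mr_noisy, b_e, c_e, tau)
        assert np.sum(tau == tau_true) >= 9
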