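"""Loss terms: hand examples, brute-force oracle, structural properties."""

import numpy as np
import pytest

from tracergan.gan_losses import (ConfigurationError, LossBreakdown,
                                  adversarial_mse, l1_term, total_loss)


class TestL1Term:
    def test_identity_is_zero(self, rng):
        x = rng.random((2, 1, 8, 8))
        assert l1_term(x, x) == 0.0

    def test_constant_offset(self):
        x = np.zeros((4, 4))
        y = np.full((4, 4), 0.25)
        assert l1_term(x, y) == pytest.approx(0.25, abs=1e-15)

    def test_hand_example(self):
        assert l1_term(np.array([0.0, 0.5]),
                       np.array([0.1, 0.9])) == pytest.approx(0.25)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            l1_term(rng.random((2, 2)), rng.random((3, 2)))


class TestAdversarialMse:
    def test_scores_at_target(self):
        assert adversarial_mse(np.full((2, 1, 4, 4), 1.0), 1.0) == 0.0

    def test_half_scores(self):
        assert adversarial_mse(np.full((3, 3), 0.5), 1.0) == pytest.approx(0.25)

    def test_mixed_scores(self):
        assert adversarial_mse(np.array([0.0, 1.0]), 1.0) == pytest.approx(0.5)

    def test_non_finite_rejected(self):
        with pytest.raises(FloatingPointError):
            adversarial_mse(np.array([np.nan, 1.0]), 1.0)


def _identity(x):
    return x


def _disc_const(value):
    def d(x):
        return np.full((x.shape[0], 1, 2, 2), value)
    return d


class TestTotalLoss:
    def test_identity_generators_zero_reconstruction_terms(self, rng):
        batch = rng.random((3, 1, 8, 8))
        bd = total_loss(batch, batch, G_A=_identity, G_B=_identity,
                        D_A=_disc_const(0.3), D_B=_disc_const(0.3))
        assert bd.cycle_A == 0.0 and bd.cycle_B == 0.0
        assert bd.identity_A == 0.0 and bd.identity_B == 0.0
        assert bd.adv_forward == pytest.approx(0.49)

    def test_exact_inverse_generators_zero_cycles(self, rng):
        a = 0.1 + 0.7 * rng.random((2, 1, 8, 8))
        b = 0.1 + 0.7 * rng.random((2, 1, 8, 8))

        def g_a(x):
            return np.clip(x + 0.1, 0, 1)

        def g_b(x):
            return np.clip(x - 0.1, 0, 1)

        bd = total_loss(a, b, G_A=g_a, G_B=g_b,
                        D_A=_disc_const(1.0), D_B=_disc_const(1.0))
        assert bd.cycle_A == pytest.approx(0.0, abs=1e-12)
        assert bd.cycle_B == pytest.approx(0.0, abs=1e-12)
        # identity terms are the deliberate 0.1 shift
        assert bd.identity_B == pytest.approx(0.1, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        """Total equals a term-by-term scalar-loop recomputation."""
        a = rng.random((2, 1, 6, 6))
        b = rng.random((2, 1, 6, 6))

        def g_a(x):
            return np.clip(0.8 * x + 0.05, 0, 1)

        def g_b(x):
            return np.clip(1.0 - x, 0, 1)

        def d(x):
            return x.mean(axis=(2, 3), keepdims=True) - 0.2

        bd = total_loss(a, b, G_A=g_a, G_B=g_b, D_A=d, D_B=d)

        def loop_l1(x, y):
            acc = 0.0
            for u, v in zip(x.ravel(), y.ravel()):
                acc += abs(u - v)
            return acc / x.size

        def loop_mse(s, t):
            acc = 0.0
            for u in s.ravel():
                acc += (u - t) ** 2
            return acc / s.size

        expected = (loop_mse(d(g_a(a)), 1.0) + loop_mse(d(g_b(b)), 1.0)
                    + loop_l1(g_b(g_a(a)), a) + loop_l1(g_a(g_b(b)), b)
                    + loop_l1(g_a(b), b) + loop_l1(g_b(a), a))
        assert bd.total == pytest.approx(expected, abs=1e-6)

    def test_batch_permutation_invariance(self, rng):
        a = rng.random((4, 1, 8, 8))
        b = rng.random((4, 1, 8, 8))
        perm = [2, 0, 3, 1]
        kw = dict(G_A=_identity, G_B=_identity,
                  D_A=_disc_const(0.5), D_B=_disc_const(0.5))
        bd1 = total_loss(a, b, **kw)
        bd2 = total_loss(a[perm], b[perm], **kw)
        assert bd1.total == pytest.approx(bd2.total, abs=1e-12)

    def test_cycle_terms_symmetric_under_domain_swap(self, rng):
        a = rng.random((2, 1, 8, 8))
        b = rng.random((2, 1, 8, 8))

        def g_a(x):
            return np.clip(1.0 - x, 0, 1)

        d = _disc_const(0.5)
        bd_ab = total_loss(a, b, G_A=g_a, G_B=g_a, D_A=d, D_B=d)
        bd_ba = total_loss(b, a, G_A=g_a, G_B=g_a, D_A=d, D_B=d)
        assert bd_ab.cycle_A == pytest.approx(bd_ba.cycle_B, abs=1e-12)
        assert bd_ab.identity_A == pytest.approx(bd_ba.identity_B, abs=1e-12)

    def test_weight_zero_removes_gradient_contribution(self):
        """Finite differences on a 2-parameter toy generator: zeroing a
        term's weight removes its gradient on the parameters."""
        rng = np.random.default_rng(0)
        a = 0.2 + 0.5 * rng.random((2, 1, 4, 4))
        b = 0.2 + 0.5 * rng.random((2, 1, 4, 4))
        d = _disc_const(0.5)

        def total_for(theta, weights):
            w1, w0 = theta

            def g_a(x):
                return np.clip(w1 * x + w0, 0, 1)

            return total_loss(a, b, G_A=g_a, G_B=_identity, D_A=d, D_B=d,
                              weights=weights).total

        eps = 1e-6
        # weights: only identity_B (index 4) active vs all-zero
        w_active = (0, 0, 0, 0, 1, 0)
        w_off = (0, 0, 0, 0, 0, 0)
        for k in range(2):
            theta_p = np.array([0.9, 0.05])
            theta_m = theta_p.copy()
            theta_p[k] += eps
            theta_m[k] -= eps
            g_active = (total_for(theta_p, w_active)
                        - total_for(theta_m, w_active)) / (2 * eps)
            g_off = (total_for(theta_p, w_off)
                     - total_for(theta_m, w_off)) / (2 * eps)
            assert abs(g_active) > 1e-3   # term really drives the params
            assert g_off == pytest.approx(0.0, abs=1e-12)

    def test_pix2pix_mode_terms(self, rng):
        a = rng.random((2, 1, 8, 8))
        b = np.clip(a + 0.2, 0, 1)
        bd = total_loss(a, b, G_A=_identity, D_A=_disc_const(1.0),
                        mode="pix2pix")
        assert bd.adv_forward == 0.0
        assert bd.cycle_A == pytest.approx(l1_term(a, b))
        assert bd.adv_backward == bd.cycle_B == 0.0
        assert bd.identity_A == bd.identity_B == 0.0

    def test_pix2pix_rejects_backward_networks(self, rng):
        a = rng.random((2, 1, 8, 8))
        with pytest.raises(ConfigurationError):
            total_loss(a, a, G_A=_identity, G_B=_identity,
                       D_A=_disc_const(1.0), mode="pix2pix")

    def test_total_is_weighted_sum(self):
        bd = LossBreakdown(adv_forward=1.0, adv_backward=2.0, cycle_A=3.0,
                           cycle_B=4.0, identity_B=5.0, identity_A=6.0,
                           weights=(1, 0.5, 10, 10, 0.5, 0.5))
        assert bd.total == pytest.approx(1 + 1 + 30 + 40 + 2.5 + 3)
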