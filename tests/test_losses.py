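"""Loss terms against closed forms and independent elementwise-loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connharm.autograd import Tensor
from connharm.losses import (cross_entropy_from_logits, cross_entropy_loss,
                             joint_loss, kl_loss, likelihood_loss,
                             reconstruction_loss)

LOG_2PI = np.log(2 * np.pi)


# -- independent loop oracles (scalar arithmetic only) ------------------------

def _ce_loop(y_hat, y):
    total = 0.0
    for j in range(len(y)):
        for c in range(len(y[j])):
            if y[j][c]:
                total -= y[j][c] * np.log(y_hat[j][c])
    return total / len(y)


def _ll_loop(x, x_hat, sigma):
    total = 0.0
    for j in range(x.shape[0]):
        for v in range(x.shape[1]):
            total += np.log(2 * np.pi * sigma[v] ** 2) \
                + (x[j, v] - x_hat[j, v]) ** 2 / (2 * sigma[v] ** 2)
    return total / (2 * x.shape[0])


def _kl_loop(mu, s):
    total = 0.0
    for j in range(mu.shape[0]):
        for d in range(mu.shape[1]):
            total += s[j, d] ** 2 + mu[j, d] ** 2 - 2 * np.log(s[j, d]) - 1
    return total / (2 * mu.shape[0])


def _lr_loop(x, alpha, gamma, delta, sigma):
    total = 0.0
    for j in range(x.shape[0]):
        for v in range(x.shape[1]):
            th = x[j, v] - alpha[v]
            total += 0.5 * (np.log(2 * np.pi * sigma[v] ** 2)
                            + th ** 2 / (2 * sigma[v] ** 2)
                            + np.log(2 * np.pi * delta[j, v] ** 2)
                            + (th - gamma[j, v]) ** 2 / (2 * delta[j, v] ** 2))
    return total / (2 * x.shape[0])


class TestClosedForms:
    def test_cross_entropy(self):
        assert cross_entropy_loss([[1.0, 0.0]], [[1, 0]]) == pytest.approx(0.0, abs=1e-10)
        assert cross_entropy_loss([[0.5, 0.5]], [[1, 0]]) == pytest.approx(np.log(2), abs=1e-10)
        a = cross_entropy_loss([[0.9, 0.1]], [[1, 0]])
        b = cross_entropy_loss([[0.2, 0.8]], [[0, 1]])
        both = cross_entropy_loss([[0.9, 0.1], [0.2, 0.8]], [[1, 0], [0, 1]])
        assert both == pytest.approx((a + b) / 2)

    def test_likelihood(self):
        assert likelihood_loss(np.zeros(1), np.zeros(1), np.ones(1)) == \
            pytest.approx(0.5 * LOG_2PI)
        base = likelihood_loss(np.array([1.0]), np.array([0.0]), np.ones(1))
        double = likelihood_loss(np.array([2.0]), np.array([0.0]), np.ones(1))
        assert double - 0.5 * LOG_2PI == pytest.approx(4 * (base - 0.5 * LOG_2PI))

    def test_kl(self):
        assert kl_loss(np.zeros(3), np.ones(3)) == pytest.approx(0.0, abs=1e-12)
        assert kl_loss(np.array([1.0]), np.array([1.0])) == pytest.approx(0.5)

    def test_reconstruction(self):
        val = reconstruction_loss(np.array([1.0]), np.array([1.0]),
                                  np.array([0.0]), np.array([1.0]), np.ones(1))
        assert val == pytest.approx(0.5 * LOG_2PI)
        # theta == gamma: the delta quadratic vanishes
        v2 = reconstruction_loss(np.array([2.0]), np.array([1.0]),
                                 np.array([1.0]), np.array([1.0]), np.ones(1))
        assert v2 == pytest.approx(0.5 * LOG_2PI + 0.125)  # ¼(2·log 2π + ½)

    def test_joint_weighted_sum(self):
        total, br = joint_loss(1.0, 1.0, 1.0, 1.0, gamma1=1e-5, gamma2=1e-3, gamma3=1e-4)
        assert total == pytest.approx(1.00111)
        total, _ = joint_loss(l_c=2.5, gamma1=0, gamma2=0, gamma3=0)
        assert total == 2.5
        total, br = joint_loss(None, 1.0, 2.0, 3.0, gamma1=0.1, gamma2=0.1, gamma3=0.1)
        assert br.l_c is None and total == pytest.approx(0.6)
        with pytest.raises(ValueError, match="nonnegative"):
            joint_loss(1.0, gamma1=-0.1)


class TestLoopOracles:
    def test_all_losses_match_loops_on_random_input(self):
        rng = np.random.default_rng(10)
        y = np.eye(2)[rng.integers(0, 2, 6)]
        y_hat = rng.dirichlet([1, 1], size=6)
        assert cross_entropy_loss(y_hat, y) == pytest.approx(_ce_loop(y_hat, y), abs=1e-10)

        x = rng.normal(size=(3, 4))
        x_hat = rng.normal(size=(3, 4))
        sigma = rng.uniform(0.5, 2, 4)
        assert likelihood_loss(x, x_hat, sigma) == pytest.approx(_ll_loop(x, x_hat, sigma), abs=1e-10)

        mu = rng.normal(size=(3, 5))
        s = rng.uniform(0.2, 3, size=(3, 5))
        assert kl_loss(mu, s) == pytest.approx(_kl_loop(mu, s), abs=1e-10)

        x = rng.normal(size=(4, 6))
        alpha = rng.normal(size=6)
        gamma = rng.normal(size=(4, 6))
        delta = rng.uniform(0.5, 2, size=(4, 6))
        assert reconstruction_loss(x, alpha, gamma, delta, sigma=rng.uniform(0.5, 2, 6) * 0 + 1.3) == \
            pytest.approx(_lr_loop(x, alpha, gamma, delta, np.full(6, 1.3)), abs=1e-10)

    def test_logit_form_matches_probability_form(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(size=(5, 2))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        y_idx = rng.integers(0, 2, 5)
        assert cross_entropy_from_logits(Tensor(logits), y_idx).item() == \
            pytest.approx(cross_entropy_loss(probs, np.eye(2)[y_idx]), abs=1e-9)


class TestProperties:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_kl_nonnegative_and_zero_only_at_prior(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.normal(size=(2, 4))
        s = rng.uniform(0.05, 4.0, size=(2, 4))
        assert kl_loss(mu, s) >= 0
        assert kl_loss(np.zeros((2, 4)), np.ones((2, 4))) == pytest.approx(0.0, abs=1e-12)
        if np.abs(mu).max() > 1e-3 or np.abs(s - 1).max() > 1e-3:
            assert kl_loss(mu, s) > 0

    def test_losses_permutation_invariant_over_subjects(self):
        rng = np.random.default_rng(8)
        x, x_hat = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        sigma = rng.uniform(0.5, 2, 3)
        perm = rng.permutation(6)
        assert likelihood_loss(x, x_hat, sigma) == pytest.approx(
            likelihood_loss(x[perm], x_hat[perm], sigma))
        mu, s = rng.normal(size=(6, 2)), rng.uniform(0.3, 2, (6, 2))
        assert kl_loss(mu, s) == pytest.approx(kl_loss(mu[perm], s[perm]))

    def test_guards(self):
        with pytest.raises(ValueError):
            likelihood_loss(np.zeros(2), np.zeros(2), np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            kl_loss(np.zeros(2), np.array([1.0, -1.0]))
        with pytest.raises(ValueError, match="labelled"):
            cross_entropy_loss(np.empty((0, 2)), np.empty((0, 2)))
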