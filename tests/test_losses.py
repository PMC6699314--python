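"""Dice-family and cross-entropy losses against scalar double-loop oracles."""

import math

import numpy as np
import pytest

from cardseg.dataio import LabelMap
from cardseg.errors import ContractError, UndefinedLossError
from cardseg.losses import (
    batch_loss_and_grad,
    cross_entropy_gradient,
    cross_entropy_loss,
    gdl_gradient,
    gdl_weights,
    generalized_dice_loss,
    igd_weights,
    improved_gdl_gradient,
    improved_generalized_dice_loss,
    one_hot_encode,
)

from conftest import random_onehot_stack, random_prob_stack

EPS = 1e-8


# ---------------------------------------------------------------------------
# independent scalar oracles (plain Python double loops over k and m)


def oracle_gdl(y, t):
    K, M = len(y), len(y[0])
    w = []
    for k in range(K):
        s = 0.0
        for m in range(M):
            s += t[k][m]
        w.append(1.0 / s**2)
    num = den = 0.0
    for k in range(K):
        sn = sd = 0.0
        for m in range(M):
            sn += y[k][m] * t[k][m]
            sd += y[k][m] ** 2 + t[k][m] ** 2
        num += w[k] * sn
        den += w[k] * sd
    return 1.0 - 2.0 * num / den


def oracle_igd(y, t, eps=EPS):
    K, M = len(y), len(y[0])
    w = []
    for k in range(K):
        st = sum(t[k][m] for m in range(M))
        if st > 0:
            w.append(1.0 / st)
        else:
            sy = sum(y[k][m] for m in range(M))
            w.append(1.0 / (sy + eps))
    num = den = 0.0
    for k in range(K):
        sn = sd = 0.0
        for m in range(M):
            sn += y[k][m] * t[k][m]
            sd += y[k][m] ** 2 + t[k][m] ** 2
        num += w[k] * sn
        den += w[k] * sd
    return 1.0 - 2.0 * (num + eps) / (den + eps)


def oracle_ce(y, t, floor=1e-12):
    K, M = len(y), len(y[0])
    total = 0.0
    for m in range(M):
        for k in range(K):
            total -= t[k][m] * math.log(y[k][m] + floor)
    return total / M


# ---------------------------------------------------------------------------


def test_one_hot_encoding_round_trip(rng):
    labels = rng.integers(1, 5, size=(6, 7))
    t = one_hot_encode(LabelMap(labels), 4)
    assert t.shape == (4, 42)
    np.testing.assert_array_equal(t.sum(axis=0), 1.0)
    recovered = t.argmax(axis=0).reshape(6, 7) + 1
    np.testing.assert_array_equal(recovered, labels)
    with pytest.raises(ContractError):
        one_hot_encode(np.array([[0]]), 4)


class TestWeights:
    def test_baseline_weight_is_inverse_square_count(self):
        t = np.zeros((2, 200))
        t[0, :100] = 1.0
        t[1, 100:] = 1.0
        np.testing.assert_allclose(gdl_weights(t), [1e-4, 1e-4])

    def test_baseline_weight_infinite_for_absent_class(self):
        t = np.zeros((3, 10))
        t[0] = 1.0  # classes 1 and 2 absent
        w = gdl_weights(t)
        assert w[0] == 1e-2
        assert np.isinf(w[1]) and np.isinf(w[2])

    def test_improved_weight_present_and_absent_rules(self, rng):
        t = np.zeros((2, 100))
        t[0] = 1.0  # class 0 has 100 px; class 1 absent
        y = np.zeros((2, 100))
        y[1] = 0.1  # total predicted mass 10 on the absent class
        w = igd_weights(y, t, EPS)
        assert w[0] == pytest.approx(1.0 / 100)
        assert w[1] == pytest.approx(1.0 / (10.0 + EPS))
        assert np.isfinite(w).all()

    def test_equal_counts_give_equal_weights(self):
        t = np.zeros((2, 8))
        t[0, :4] = 1.0
        t[1, 4:] = 1.0
        w = gdl_weights(t)
        assert w[0] == w[1]


class TestGeneralizedDice:
    def test_perfect_prediction_gives_zero_loss(self, rng):
        t = random_onehot_stack(rng, 4, 32, present_all=True)
        assert generalized_dice_loss(t.copy(), t) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_prediction_gives_unit_loss(self):
        t = np.zeros((2, 4))
        t[0] = 1.0
        y = np.zeros((2, 4))
        y[1] = 1.0
        # make truth contain both classes to keep weights finite
        t[0, 3] = 0.0
        t[1, 3] = 1.0
        y[0, 3] = 1.0
        y[1, 3] = 0.0
        assert generalized_dice_loss(y, t) == pytest.approx(1.0, abs=1e-9)

    def test_absent_class_raises(self, rng):
        t = np.zeros((4, 16))
        t[0] = 1.0
        y = random_prob_stack(rng, 4, 16)
        with pytest.raises(UndefinedLossError):
            generalized_dice_loss(y, t)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            y = random_prob_stack(rng, 4, 16)
            t = random_onehot_stack(rng, 4, 16, present_all=True)
            assert generalized_dice_loss(y, t) == pytest.approx(
                oracle_gdl(y.tolist(), t.tolist()), abs=1e-10
            )


class TestImprovedGeneralizedDice:
    def test_perfect_prediction_with_absent_class(self, rng):
        t = random_onehot_stack(rng, 4, 32)
        t[3] = 0.0  # remove class 4 entirely
        t[0] = np.where(t.sum(axis=0) == 0, 1.0, t[0])
        y = t.copy()
        assert improved_generalized_dice_loss(y, t) <= 1e-6

    def test_uniform_prediction_is_finite_and_interior(self, rng):
        t = random_onehot_stack(rng, 4, 64)
        y = np.full((4, 64), 0.25)
        loss = improved_generalized_dice_loss(y, t)
        assert 0.0 < loss < 1.0

    def test_matches_double_loop_oracle_with_absent_class(self, rng):
        for _ in range(20):
            y = random_prob_stack(rng, 4, 16)
            labels = rng.integers(0, 3, size=16)  # class 4 never appears
            t = np.zeros((4, 16))
            t[labels, np.arange(16)] = 1.0
            assert improved_generalized_dice_loss(y, t) == pytest.approx(
                oracle_igd(y.tolist(), t.tolist()), abs=1e-10
            )

    def test_near_zero_prediction_on_absent_class_keeps_loss_finite(self, rng):
        t = random_onehot_stack(rng, 4, 32)
        t[3] = 0.0
        t[0] = np.where(t.sum(axis=0) == 0, 1.0, t[0])
        y = random_prob_stack(rng, 4, 32)
        y[3] = 1e-12  # prediction also near zero for the absent class
        y /= y.sum(axis=0, keepdims=True)
        loss = improved_generalized_dice_loss(y, t)
        assert np.isfinite(loss)
        assert -1e-6 <= loss <= 1.0 + 1e-6

    def test_invariant_under_joint_class_relabeling(self, rng):
        y = random_prob_stack(rng, 4, 24)
        t = random_onehot_stack(rng, 4, 24)
        perm = rng.permutation(4)
        a = improved_generalized_dice_loss(y, t)
        b = improved_generalized_dice_loss(y[perm], t[perm])
        assert a == pytest.approx(b, abs=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            y = random_prob_stack(rng, 4, 16)
            t = random_onehot_stack(rng, 4, 16)
            loss = improved_generalized_dice_loss(y, t)
            assert -1e-6 <= loss <= 1.0 + 1e-6


class TestCrossEntropy:
    def test_perfect_one_hot_prediction_is_near_zero(self, rng):
        t = random_onehot_stack(rng, 4, 32)
        assert cross_entropy_loss(t.copy(), t) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_equals_log_k(self, rng):
        t = random_onehot_stack(rng, 4, 32)
        y = np.full((4, 32), 0.25)
        assert cross_entropy_loss(y, t) == pytest.approx(math.log(4), abs=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            y = random_prob_stack(rng, 4, 16)
            t = random_onehot_stack(rng, 4, 16)
            assert cross_entropy_loss(y, t) == pytest.approx(
                oracle_ce(y.tolist(), t.tolist()), abs=1e-10
            )


class TestGradients:
    @staticmethod
    def _fd_grad(fn, y, h=1e-7):
        g = np.zeros_like(y)
        for k in range(y.shape[0]):
            for m in range(y.shape[1]):
                yp = y.copy()
                yp[k, m] += h
                ym = y.copy()
                ym[k, m] -= h
                g[k, m] = (fn(yp) - fn(ym)) / (2 * h)
        return g

    def test_improved_loss_gradient_matches_finite_differences(self, rng):
        y = random_prob_stack(rng, 3, 6)
        t = random_onehot_stack(rng, 3, 6)
        t[2] = 0.0  # absent class exercises the dw/dY term
        t[0] = np.where(t.sum(axis=0) == 0, 1.0, t[0])
        analytic = improved_gdl_gradient(y, t)
        fd = self._fd_grad(lambda yy: improved_generalized_dice_loss(yy, t), y)
        np.testing.assert_allclose(analytic, fd, rtol=1e-4, atol=1e-8)

    def test_baseline_and_ce_gradients_match_finite_differences(self, rng):
        y = random_prob_stack(rng, 3, 6)
        t = random_onehot_stack(rng, 3, 6, present_all=True)
        np.testing.assert_allclose(
            gdl_gradient(y, t),
            self._fd_grad(lambda yy: generalized_dice_loss(yy, t), y),
            rtol=1e-4,
            atol=1e-8,
        )
        np.testing.assert_allclose(
            cross_entropy_gradient(y, t),
            self._fd_grad(lambda yy: cross_entropy_loss(yy, t), y),
            rtol=1e-4,
            atol=1e-8,
        )


def test_batch_interface_averages_per_item(rng):
    probs = rng.random((2, 4, 4, 4))
    probs /= probs.sum(axis=-1, keepdims=True)
    labels = rng.integers(1, 5, (2, 4, 4))
    total, grads = batch_loss_and_grad(probs, labels, "igd")
    per_item = [
        improved_generalized_dice_loss(
            probs[i].reshape(-1, 4).T, one_hot_encode(labels[i], 4)
        )
        for i in range(2)
    ]
    assert total == pytest.approx(np.mean(per_item), abs=1e-12)
    assert grads.shape == probs.shape
    with pytest.raises(ContractError):
        batch_loss_and_grad(probs, labels, "nope")
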