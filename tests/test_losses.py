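import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plantseg3d import (combined_loss, cross_entropy_loss, separation_loss,
                        separation_penalty)
from plantseg3d.autodiff import Tensor
from plantseg3d.errors import ValidationError


def sep_oracle(heads):
    """Explicit double-loop cosine reference."""
    flat = [np.asarray(h).ravel() for h in heads]
    h = len(flat)
    total = 0.0
    for i in range(h):
        for j in range(h):
            if i != j:
                total += abs(flat[i] @ flat[j]) / (
                    np.linalg.norm(flat[i]) * np.linalg.norm(flat[j]))
    return -total / h ** 2


class TestSeparationLoss:
    def test_identical_heads_hit_lower_bound(self):
        f = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert separation_loss([f, f.copy()]).item() == pytest.approx(-0.5)

    def test_orthogonal_heads_give_zero(self):
        val = separation_loss([np.array([1.0, 0.0]),
                               np.array([0.0, 1.0])]).item()
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_three_head_hand_computed_case(self):
        heads = [np.array([1.0, 0.0]), np.array([1.0, 1.0]) / np.sqrt(2),
                 np.array([0.0, 1.0])]
        expected = -4.0 / (9.0 * np.sqrt(2))       # = -0.31427...
        assert separation_loss(heads).item() == pytest.approx(expected,
                                                              abs=1e-12)
        assert separation_loss(heads).item() == pytest.approx(
            sep_oracle(heads), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(2, 5), st.integers(0, 10 ** 6))
    def test_bounds_and_oracle_on_random_fixtures(self, h, seed):
        rng = np.random.default_rng(seed)
        heads = [rng.normal(size=(3, 4)) for _ in range(h)]
        val = separation_loss(heads).item()
        assert -(h - 1) / h - 1e-9 <= val <= 1e-12
        assert val == pytest.approx(sep_oracle(heads), abs=1e-9)

    def test_lower_bound_iff_pairwise_parallel(self, rng):
        base = rng.normal(size=(2, 3))
        heads = [2.0 * base, -0.5 * base, base]
        assert separation_loss(heads).item() == pytest.approx(-2.0 / 3.0)

    def test_invariant_to_positive_per_head_rescaling(self, rng):
        heads = [rng.normal(size=(2, 5)) for _ in range(3)]
        scaled = [s * h for s, h in zip((0.1, 7.0, 300.0), heads)]
        assert separation_loss(scaled).item() == pytest.approx(
            separation_loss(heads).item(), rel=1e-9)

    def test_finite_difference_gradient(self, rng):
        heads = [Tensor(rng.normal(size=(2, 3)), requires_grad=True)
                 for _ in range(3)]
        separation_loss(heads).backward()
        eps = 1e-6
        for t in heads:
            num = np.zeros_like(t.data)
            it = np.nditer(t.data, flags=["multi_index"])
            while not it.finished:
                i = it.multi_index
                orig = t.data[i]
                t.data[i] = orig + eps
                up = separation_loss([x.detach() for x in heads]).item()
                t.data[i] = orig - eps
                dn = separation_loss([x.detach() for x in heads]).item()
                t.data[i] = orig
                num[i] = (up - dn) / (2 * eps)
                it.iternext()
            rel = np.abs(num - t.grad).max() / (np.abs(num).max() + 1e-12)
            assert rel < 1e-4

    def test_zero_norm_head_contributes_nothing(self, caplog):
        heads = [np.array([1.0, 0.0]), np.zeros(2), np.array([1.0, 0.0])]
        with caplog.at_level(logging.WARNING):
            val = separation_loss(heads).item()
        assert val == pytest.approx(-2.0 / 9.0)     # only the (0,2) pairs
        assert "zero norm" in caplog.text

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            separation_loss([np.ones(3)])
        with pytest.raises(ValidationError):
            separation_loss([np.zeros(3), np.zeros(3)])
        with pytest.raises(ValidationError):
            separation_loss([np.ones(3), np.ones(4)])

    def test_penalty_is_negated_loss(self, rng):
        heads = [rng.normal(size=(2, 2)) for _ in range(3)]
        assert separation_penalty(heads).item() == pytest.approx(
            -separation_loss(heads).item())


class TestCrossEntropy:
    def test_perfect_prediction_zero_both_modes(self):
        logits = np.eye(3)[np.array([0, 1, 2])] * 60.0
        labels = np.array([0, 1, 2])
        for mode in ("categorical", "literal"):
            assert cross_entropy_loss(logits, labels, mode=mode).item() == \
                pytest.approx(0.0, abs=1e-10)

    def test_uniform_prediction_is_log3(self):
        logits = np.zeros((7, 3))
        labels = np.array([0, 1, 2, 0, 1, 2, 0])
        assert cross_entropy_loss(logits, labels).item() == \
            pytest.approx(np.log(3.0))

    def test_matches_per_point_loop_oracle(self, rng):
        logits = rng.normal(size=(10, 3))
        labels = rng.integers(0, 3, 10)
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        expected = np.mean([-np.log(p[i, labels[i]]) for i in range(10)])
        assert cross_entropy_loss(logits, labels).item() == \
            pytest.approx(expected, abs=1e-6)
        lit = np.mean([-np.log(p[i, labels[i]])
                       - sum(np.log(1 - p[i, c]) for c in range(3)
                             if c != labels[i]) for i in range(10)])
        assert cross_entropy_loss(logits, labels, mode="literal").item() == \
            pytest.approx(lit, abs=1e-6)

    def test_label_validation(self, rng):
        logits = rng.normal(size=(4, 3))
        with pytest.raises(ValidationError):
            cross_entropy_loss(logits, np.array([0, 1, 2, 3]))
        with pytest.raises(ValidationError):
            cross_entropy_loss(logits, np.array([0, 1]))


class TestCombinedLoss:
    def test_zero_weight_reduces_to_cross_entropy(self, rng):
        logits = rng.normal(size=(6, 3))
        labels = rng.integers(0, 3, 6)
        heads = [[rng.normal(size=(2, 2)) for _ in range(2)]]
        bd = combined_loss(logits, labels, heads, loss_scal=0.0)
        assert bd.total_value == bd.cross_entropy_value

    def test_orthogonal_heads_leave_total_at_ce(self, rng):
        logits = rng.normal(size=(6, 3))
        labels = rng.integers(0, 3, 6)
        heads = [[np.array([1.0, 0.0]), np.array([0.0, 1.0])]]
        bd = combined_loss(logits, labels, heads, loss_scal=1.0)
        assert bd.separation_value == pytest.approx(0.0, abs=1e-12)
        assert bd.total_value == pytest.approx(bd.cross_entropy_value)

    def test_breakdown_arithmetic(self, rng):
        # ce ~ known, separation -0.5 (identical heads), scal 1 →
        # total = ce + 0.5 (the separation term enters as a penalty)
        logits = rng.normal(size=(5, 3))
        labels = rng.integers(0, 3, 5)
        f = rng.normal(size=(2, 2))
        bd = combined_loss(logits, labels, [[f, f.copy()]], loss_scal=1.0)
        assert bd.separation_value == pytest.approx(-0.5)
        assert bd.total_value == pytest.approx(bd.cross_entropy_value + 0.5)

    def test_mean_over_modules(self, rng):
        logits = rng.normal(size=(5, 3))
        labels = rng.integers(0, 3, 5)
        f = rng.normal(size=(2, 2))
        ortho = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        bd = combined_loss(logits, labels, [[f, f.copy()], ortho],
                           loss_scal=1.0)
        assert bd.separation_value == pytest.approx(-0.25)

    def test_empty_heads_list_rejected(self, rng):
        with pytest.raises(ValidationError):
            combined_loss(rng.normal(size=(3, 3)), np.array([0, 1, 2]), [])
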