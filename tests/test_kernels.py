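"""Kernel construction, centering, the alignment statistic, and its gradient."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckalign import (
    center_kernel,
    cka,
    cka_cost_and_gradient,
    label_kernel,
    projected_gaussian_kernel,
)
from ckalign.exceptions import (
    DegenerateKernelError,
    DegenerateLabelsError,
    ParameterError,
    ShapeError,
)

from conftest import center_elementwise, cka_bruteforce


class TestProjectedGaussianKernel:
    def test_unit_diagonal_and_range(self, rng):
        X = rng.normal(size=(12, 5))
        W = rng.normal(size=(5, 3))
        K = projected_gaussian_kernel(X, W, sigma=1.3)
        assert np.allclose(np.diag(K), 1.0)
        assert np.allclose(K, K.T)
        assert np.all(K > 0) and np.all(K <= 1)

    def test_identical_rows_give_one(self, rng):
        X = rng.normal(size=(4, 3))
        X[2] = X[0]
        K = projected_gaussian_kernel(X, np.eye(3), sigma=0.7)
        assert K[0, 2] == pytest.approx(1.0)

    def test_hand_value_two_points(self):
        # distance 1, sigma 1: off-diagonal exp(-1/2)
        K = projected_gaussian_kernel(np.array([[0.0], [1.0]]), np.array([[1.0]]), 1.0)
        assert K[0, 1] == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_depends_on_W_only_through_WWt(self, rng):
        X = rng.normal(size=(8, 4))
        W = rng.normal(size=(4, 3))
        # random orthogonal Q via QR
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        K1 = projected_gaussian_kernel(X, W, 2.0)
        K2 = projected_gaussian_kernel(X, W @ Q, 2.0)
        np.testing.assert_allclose(K1, K2, atol=1e-12)

    def test_positive_semidefinite(self, rng):
        X = rng.normal(size=(10, 3))
        K = projected_gaussian_kernel(X, np.eye(3), 1.0)
        eigs = np.linalg.eigvalsh(K)
        assert eigs.min() >= -1e-10 * np.trace(K)

    @pytest.mark.parametrize("sigma", [0.0, -1.0, np.nan])
    def test_bad_sigma(self, sigma):
        with pytest.raises(ParameterError):
            projected_gaussian_kernel(np.zeros((3, 2)), np.eye(2), sigma)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            projected_gaussian_kernel(np.zeros((3, 2)), np.zeros((4, 1)), 1.0)


class TestLabelKernel:
    def test_delta_blocks(self):
        K = label_kernel(np.array(["a", "a", "b"]))
        np.testing.assert_array_equal(K, [[1, 1, 0], [1, 1, 0], [0, 0, 1]])

    def test_all_distinct_is_identity(self):
        K = label_kernel(np.arange(4))
        np.testing.assert_array_equal(K, np.eye(4))

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            label_kernel(np.array(["a", "a", "a"]))

    def test_centered_frobenius_norm_balanced_two_class(self):
        # oracle: elementwise-centered delta kernel of [a,a,b,b]
        K = label_kernel(np.array(["a", "a", "b", "b"]))
        Kc = center_elementwise(K)
        expected = float(np.sum(Kc * Kc))
        got = float(np.sum(center_kernel(K) ** 2))
        assert got == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4.0)  # 16 entries of magnitude 1/2


class TestCenterKernel:
    def test_constant_kernel_annihilated(self):
        assert np.allclose(center_kernel(np.ones((3, 3))), 0.0)

    def test_identity_two_by_two(self):
        np.testing.assert_allclose(
            center_kernel(np.eye(2)), [[0.5, -0.5], [-0.5, 0.5]]
        )

    def test_matches_elementwise_oracle(self, rng):
        A = rng.normal(size=(5, 5))
        K = A + A.T
        np.testing.assert_allclose(center_kernel(K), center_elementwise(K), atol=1e-12)

    def test_zero_row_and_column_sums(self, rng):
        K = rng.normal(size=(7, 7))
        K = K + K.T
        Kc = center_kernel(K)
        assert np.allclose(Kc.sum(axis=0), 0, atol=1e-10)
        assert np.allclose(Kc.sum(axis=1), 0, atol=1e-10)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=2, max_value=10), st.integers(0, 2**32 - 1))
    def test_idempotent(self, n, seed):
        K = np.random.default_rng(seed).normal(size=(n, n))
        K = K + K.T
        Kc = center_kernel(K)
        np.testing.assert_allclose(center_kernel(Kc), Kc, atol=1e-10)

    def test_non_square_raises(self):
        with pytest.raises(ShapeError):
            center_kernel(np.zeros((3, 4)))


class TestCka:
    def test_self_alignment_is_one(self, rng):
        X = rng.normal(size=(6, 2))
        K = projected_gaussian_kernel(X, np.eye(2), 1.0)
        a = cka(K, K)
        assert a.rho == pytest.approx(1.0)
        assert a.cost == pytest.approx(0.0, abs=1e-12)

    def test_crossed_labels_brute_force(self):
        # N=4 derived example: alignment of two crossed two-class delta kernels
        Kl = label_kernel(np.array(["a", "a", "b", "b"]))
        Kx = label_kernel(np.array(["a", "b", "a", "b"]))
        expected = cka_bruteforce(Kx, Kl)
        assert cka(Kx, Kl).rho == pytest.approx(max(expected, 0.0), abs=1e-12)
        # these block structures are orthogonal after centering
        assert expected == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        A = rng.normal(size=(5, 5)); A = A @ A.T
        B = rng.normal(size=(5, 5)); B = B @ B.T
        assert cka(A, B).rho == pytest.approx(cka(B, A).rho, rel=1e-12)

    def test_invariant_to_scale_and_constant_shift(self, rng):
        A = rng.normal(size=(6, 6)); A = A @ A.T
        B = rng.normal(size=(6, 6)); B = B @ B.T
        base = cka(A, B).rho
        assert cka(3.7 * A, B).rho == pytest.approx(base, rel=1e-10)
        assert cka(A + 5.0, B).rho == pytest.approx(base, rel=1e-10)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=3, max_value=12), st.integers(0, 2**32 - 1))
    def test_rho_in_unit_interval(self, n, seed):
        r = np.random.default_rng(seed)
        A = r.normal(size=(n, n)); A = A @ A.T
        B = r.normal(size=(n, n)); B = B @ B.T
        a = cka(A, B)
        assert 0.0 <= a.rho <= 1.0
        assert a.cost >= 0.0

    def test_degenerate_constant_kernel_raises(self):
        with pytest.raises(DegenerateKernelError):
            cka(np.ones((4, 4)), label_kernel(np.array(["a", "a", "b", "b"])))

    def test_trace_identity_equals_centered_frobenius(self, rng):
        # tr(Kx H Kl H) == <H Kx H, H Kl H>_F, the two printed routes
        for _ in range(100):
            n = int(rng.integers(3, 9))
            A = rng.normal(size=(n, n)); A = A + A.T
            B = rng.normal(size=(n, n)); B = B + B.T
            H = np.eye(n) - np.ones((n, n)) / n
            lhs = np.trace(A @ H @ B @ H)
            rhs = float(np.sum(center_kernel(A) * center_kernel(B)))
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-10)


def finite_difference_gradient(f, W, eps=1e-6):
    g = np.zeros_like(W)
    for i in range(W.shape[0]):
        for j in range(W.shape[1]):
            Wp = W.copy(); Wp[i, j] += eps
            Wm = W.copy(); Wm[i, j] -= eps
            g[i, j] = (f(Wp) - f(Wm)) / (2 * eps)
    return g


class TestCostGradient:
    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_finite_differences(self, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(10, 4))
        W = 0.5 * r.normal(size=(4, 2))
        labels = r.integers(0, 2, size=10)
        labels[:2] = [0, 1]
        Klc = center_kernel(label_kernel(labels))
        cost, grad, _ = cka_cost_and_gradient(W, X, Klc, sigma=1.2)
        fd = finite_difference_gradient(
            lambda w: cka_cost_and_gradient(w, X, Klc, 1.2)[0], W
        )
        np.testing.assert_allclose(grad, fd, rtol=1e-4, atol=1e-7)

    def test_gradient_orthogonal_to_rotation_symmetry(self, rng):
        # cost(WQ) = cost(W) for orthogonal Q, so <grad, W A> = 0 for
        # antisymmetric A (the tangent of the rotation orbit)
        X = rng.normal(size=(9, 5))
        W = rng.normal(size=(5, 3)) * 0.4
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        Klc = center_kernel(label_kernel(labels))
        _, grad, _ = cka_cost_and_gradient(W, X, Klc, 1.0)
        A = rng.normal(size=(3, 3))
        A = A - A.T
        assert abs(np.sum(grad * (W @ A))) < 1e-8 * np.linalg.norm(grad) * np.linalg.norm(W @ A)

    def test_numerically_constant_kernel_raises(self, rng):
        X = rng.normal(size=(8, 3))
        W = rng.normal(size=(3, 2))
        Klc = center_kernel(label_kernel(np.array([0, 1] * 4)))
        with pytest.raises(DegenerateKernelError, match="bandwidth"):
            cka_cost_and_gradient(W, X, Klc, sigma=1e9)
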