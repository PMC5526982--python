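"""Kernel construction, centering, and the centered-kernel-alignment statistic.

The central quantity is the empirical centered kernel alignment (CKA)
between two N×N kernel matrices,

    rho_hat = <K̄_X, K̄_L>_F / sqrt(<K̄_X, K̄_X>_F <K̄_L, K̄_L>_F),

where K̄ = H K H is the double-centered kernel, H = I - 11^T/N. rho_hat
lies in [0, 1] by Cauchy–Schwarz; it is 1 when the two kernels agree up to
centering and scale, and 0 when their centered forms are orthogonal. With a
class-indicator label kernel, rho_hat is an HSIC-style class-separability
score: maximizing it over a projection makes same-class samples similar and
different-class samples dissimilar under the projected Gaussian kernel

    k(x, x') = exp(-(x - x') W W^T (x - x')^T / (2 sigma^2)).

The learning objective is cost = -log(rho_hat); its gradient with respect
to W is derived analytically here and is the workhorse of both the linear
metric fit and the layer-wise network pretraining.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import (
    DegenerateKernelError,
    DegenerateLabelsError,
    ParameterError,
    ShapeError,
)

__all__ = [
    "Alignment",
    "projected_gaussian_kernel",
    "label_kernel",
    "center_kernel",
    "cka",
    "cka_cost_and_gradient",
    "cost_and_kernel_gradient",
    "distance_laplacian",
    "projected_squared_distances",
    "RHO_FLOOR",
]

#: Lower clip on rho_hat before taking the log, keeping the cost finite
#: during early iterations where the alignment may round to zero.
RHO_FLOOR = 1e-12


class Alignment(NamedTuple):
    """CKA value and the associated learning cost."""

    rho: float
    cost: float  # -log(rho), floored at -log(RHO_FLOOR)


def projected_squared_distances(X: np.ndarray, W: np.ndarray | None = None) -> np.ndarray:
    """Pairwise squared Euclidean distances of X (optionally after X @ W)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ShapeError(f"X must be 2-D, got shape {X.shape}")
    if W is not None:
        W = np.asarray(W, dtype=float)
        if W.ndim != 2 or W.shape[0] != X.shape[1]:
            raise ShapeError(
                f"projection shape {W.shape} incompatible with {X.shape[1]} features"
            )
        X = X @ W
    if X.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(X, metric="sqeuclidean"))


def projected_gaussian_kernel(
    X: np.ndarray, W: np.ndarray | None, sigma: float
) -> np.ndarray:
    """Gaussian kernel on linearly projected features.

    Entry (n, n') is exp(-||(x_n - x_n') W||^2 / (2 sigma^2)); with W = None
    the plain Gaussian kernel on X. Symmetric with unit diagonal.
    """
    if not np.isfinite(sigma) or sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    D = projected_squared_distances(X, W)
    K = np.exp(-D / (2.0 * sigma**2))
    np.fill_diagonal(K, 1.0)
    return K


def label_kernel(labels: np.ndarray) -> np.ndarray:
    """Class-indicator (delta) kernel: 1 for same-class pairs, else 0.

    Block-structured by class, positive semidefinite. Raises
    :class:`DegenerateLabelsError` for single-class input, whose centered
    kernel would vanish and leave the alignment undefined.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ShapeError("labels must be a 1-D vector")
    if np.unique(labels).size < 2:
        raise DegenerateLabelsError(
            "label kernel needs at least two classes; the centered kernel of "
            "a single class is identically zero"
        )
    return (labels[:, None] == labels[None, :]).astype(float)


def center_kernel(K: np.ndarray) -> np.ndarray:
    """Double-center a kernel matrix: K̄ = H K H with H = I - 11^T/N.

    Equivalently, subtract row means, column means, and add back the grand
    mean elementwise. Idempotent; output rows and columns sum to zero.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ShapeError(f"kernel must be square, got shape {K.shape}")
    row = K.mean(axis=1, keepdims=True)
    col = K.mean(axis=0, keepdims=True)
    return K - row - col + K.mean()


def _centered_sq_norm(Kc: np.ndarray) -> float:
    return float(np.sum(Kc * Kc))


def cka(Kx: np.ndarray, Kl: np.ndarray) -> Alignment:
    """Empirical centered kernel alignment between two kernel matrices.

    Returns rho in [0, 1] (clipped against round-off) and cost = -log(rho).
    Either argument may be passed already centered; centering is idempotent
    so the result is unchanged.
    """
    Kx = np.asarray(Kx, dtype=float)
    Kl = np.asarray(Kl, dtype=float)
    if Kx.shape != Kl.shape or Kx.ndim != 2 or Kx.shape[0] != Kx.shape[1]:
        raise ShapeError(f"kernels must be square and same shape, got {Kx.shape} / {Kl.shape}")
    Kxc = center_kernel(Kx)
    Klc = center_kernel(Kl)
    nx = _centered_sq_norm(Kxc)
    nl = _centered_sq_norm(Klc)
    scale = max(np.abs(Kx).max(), 1.0) * Kx.shape[0]
    if nx <= (1e-15 * scale) ** 2 or nl <= (1e-15 * scale) ** 2:
        raise DegenerateKernelError(
            "a centered kernel is numerically zero (constant kernel or "
            "single class); the alignment is undefined"
        )
    rho = float(np.sum(Kxc * Klc)) / np.sqrt(nx * nl)
    rho = float(np.clip(rho, 0.0, 1.0))
    cost = -np.log(max(rho, RHO_FLOOR))
    return Alignment(rho=rho, cost=float(cost))


def cka_cost_and_gradient(
    W: np.ndarray,
    X: np.ndarray,
    Kl_centered: np.ndarray,
    sigma: float,
) -> tuple[float, np.ndarray, float]:
    """Cost -log rho_hat(K̄_X(W), K̄_L), its analytic gradient in W, and rho.

    Writing u = <K̄_X, K̄_L>_F and v = <K̄_X, K̄_X>_F, the cost is
    -log u + (1/2) log v up to a constant. Because double-centering is a
    self-adjoint idempotent map, d cost/dK = -K̄_L/u + K̄_X/v =: G, and with
    S = G ∘ K the Gaussian-kernel chain rule collapses to a graph-Laplacian
    form:

        grad = -(2 / sigma^2) X^T (diag(S 1) - S) X W.

    Correctness is pinned by finite-difference tests in the suite.
    """
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    Klc = np.asarray(Kl_centered, dtype=float)
    K = projected_gaussian_kernel(X, W, sigma)
    cost, G, rho = cost_and_kernel_gradient(K, Klc)
    L = distance_laplacian(G, K)
    grad = (-2.0 / sigma**2) * (X.T @ (L @ X)) @ W
    return cost, grad, rho


def cost_and_kernel_gradient(
    K: np.ndarray, Kl_centered: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Cost -log rho_hat and its gradient with respect to the kernel entries.

    Shared by the linear and the saturated (network-layer) paths; the caller
    chains d cost/dK through its own parameterization of K.
    """
    Klc = np.asarray(Kl_centered, dtype=float)
    Kc = center_kernel(K)
    v = _centered_sq_norm(Kc)
    nl = _centered_sq_norm(Klc)
    if nl <= 0:
        raise DegenerateKernelError("centered label kernel is zero")
    n = K.shape[0]
    if v <= (1e-14 * n) ** 2:
        raise DegenerateKernelError(
            "Gaussian kernel is numerically constant (centered kernel ~ 0); "
            "re-tune the bandwidth sigma"
        )
    u = float(np.sum(Kc * Klc))
    denom = np.sqrt(v * nl)
    rho = u / denom
    u_safe = max(u, RHO_FLOOR * denom)  # keeps cost/grad finite when rho <= 0
    cost = float(-np.log(u_safe / denom))
    G = -Klc / u_safe + Kc / v
    return cost, G, float(np.clip(rho, 0.0, 1.0))


def distance_laplacian(G: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Graph Laplacian of S = G ∘ K, the squared-distance sensitivity.

    For any representation Y with Gaussian kernel K on its pairwise squared
    distances, d cost/dY = (-2/sigma^2) L Y. Diagonal terms cancel (zero
    self-distance), so the Laplacian form is exact.
    """
    S = G * K
    return np.diag(S.sum(axis=1)) - S
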