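"""Linear metric learning by CKA maximization.

Fits a projection W (P×d) and Gaussian bandwidth sigma so that the kernel
on the projected features aligns maximally with the class-indicator kernel,
i.e. minimizes -log rho_hat. The induced generalized Euclidean
(Mahalanobis-type) distance is (x - x') W W^T (x - x')^T; equivalently,
plain Euclidean distance after the linear map y = x W.

Features are z-scored internally before fitting (the intended inputs mix
mm^3, mm^2 and mm units, and the principal-component initialization is
meaningless across heterogeneous scales); the standardization is stored on
the model and re-applied by :func:`transform`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist

from .data import FeatureMatrix
from .exceptions import DegenerateGeometryError, ParameterError, ShapeError
from .kernels import center_kernel, cka_cost_and_gradient, label_kernel

__all__ = [
    "FitConfig",
    "MetricModel",
    "pca_init",
    "tune_bandwidth",
    "fit_metric",
    "transform",
]


@dataclass
class FitConfig:
    """Optimizer settings for the CKA projection fit.

    d : target dimension; None picks min(P, 3*C) — alignment with a C-class
        label kernel needs only low rank, extra dimensions ease optimization.
    max_iters : full-batch iteration (or epoch) cap.
    learning_rate : initial step size for the backtracking search.
    batch_size : None for full-batch gradient descent (monotone by
        construction); an integer enables minibatch stochastic gradient,
        with the cost still recorded full-batch once per epoch.
    tolerance : relative cost-change convergence threshold.
    bandwidth_strategy : "median" (median positive projected pairwise
        distance) or "kernel-variance" (maximize the empirical variance of
        off-diagonal kernel entries over a log-spaced grid around the
        median).
    """

    d: int | None = None
    max_iters: int = 200
    learning_rate: float = 1.0
    batch_size: int | None = None
    tolerance: float = 1e-6
    seed: int = 0
    bandwidth_strategy: str = "median"

    def __post_init__(self) -> None:
        if self.max_iters <= 0 or self.learning_rate <= 0 or self.tolerance <= 0:
            raise ParameterError("max_iters, learning_rate and tolerance must be positive")
        if self.batch_size is not None and self.batch_size <= 0:
            raise ParameterError("batch_size must be positive or None")


@dataclass
class MetricModel:
    """Learned projection, bandwidth, and standardization.

    ``fit_history`` holds (iteration, cost) pairs; with the default
    full-batch optimizer the cost sequence is non-increasing across
    accepted steps. ``converged`` is False when the iteration cap was hit
    before the tolerance — a warning status, not an error.
    """

    W: np.ndarray
    sigma: float
    d: int
    mean_: np.ndarray
    scale_: np.ndarray
    fit_history: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0
    converged: bool = True
    rho_init: float = float("nan")
    rho_final: float = float("nan")

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.mean_.size:
            raise ShapeError(
                f"expected {self.mean_.size} features, got shape {X.shape}"
            )
        return (X - self.mean_) / self.scale_


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant features pass through
    return (X - mean) / scale, mean, scale


def pca_init(X: np.ndarray, d: int) -> np.ndarray:
    """Top-d principal directions of X as a P×d orthonormal projection.

    Deterministic: eigendecomposition of the covariance, eigenvalue order
    descending, sign fixed so each column's largest-magnitude element is
    positive. X is expected standardized (or at least commensurate) —
    :func:`fit_metric` handles that.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= d <= min(p, max(n - 1, 1)):
        raise ParameterError(f"d={d} out of range [1, min(P={p}, N-1={n - 1})]")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / max(n - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:d]
    W = vecs[:, order]
    for j in range(W.shape[1]):
        i = np.argmax(np.abs(W[:, j]))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return W


def tune_bandwidth(
    X: np.ndarray, W: np.ndarray | None = None, strategy: str = "median"
) -> float:
    """Gaussian bandwidth on the scale of projected pairwise distances.

    "median": the median of the positive pairwise Euclidean distances of
    X @ W (zero distances from duplicated samples are excluded, so
    duplicating every sample leaves sigma unchanged). "kernel-variance":
    scans a log-spaced grid around the median value and returns the sigma
    maximizing the empirical variance of the off-diagonal kernel entries.
    Both are deterministic.
    """
    X = np.asarray(X, dtype=float)
    Y = X if W is None else X @ np.asarray(W, dtype=float)
    dist = pdist(Y, metric="euclidean")
    pos = dist[dist > 0]
    if pos.size == 0:
        raise DegenerateGeometryError(
            "all projected points coincide; no distance scale to tune on"
        )
    med = float(np.median(pos))
    if strategy == "median":
        return med
    if strategy == "kernel-variance":
        best_sigma, best_var = med, -1.0
        for s in med * np.logspace(-1.5, 1.5, 31):
            k = np.exp(-(dist**2) / (2.0 * s**2))
            v = float(np.var(k))
            if v > best_var:
                best_var, best_sigma = v, float(s)
        return best_sigma
    raise ParameterError(f"unknown bandwidth strategy {strategy!r}")


def _descend(
    objective: Callable[[np.ndarray], tuple[float, np.ndarray, float]],
    W0: np.ndarray,
    config: FitConfig,
) -> tuple[np.ndarray, list[tuple[int, float]], bool, float, float]:
    """Full-batch gradient descent with backtracking line search.

    Accepts a step only if it satisfies a sufficient-decrease (Armijo)
    condition, so the recorded cost sequence is non-increasing. Returns
    (W, history, converged, rho_init, rho_final).
    """
    W = W0.copy()
    cost, grad, rho0 = objective(W)
    history = [(0, cost)]
    last_step = config.learning_rate
    converged = False
    rho = rho0
    for it in range(1, config.max_iters + 1):
        gnorm2 = float(np.sum(grad * grad))
        if gnorm2 <= 1e-30:
            converged = True
            break
        # start each search above the last accepted step so a transient
        # collapse of the step size cannot persist as a slow crawl
        step = min(4.0 * last_step, config.learning_rate)
        accepted = False
        while step > 1e-15:
            W_try = W - step * grad
            try:
                c_try, g_try, r_try = objective(W_try)
            except Exception:
                step *= 0.5
                continue
            if c_try <= cost - 1e-4 * step * gnorm2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # no admissible descent step: at a local optimum
            break
        rel = (cost - c_try) / max(abs(cost), 1e-12)
        W, cost, grad, rho = W_try, c_try, g_try, r_try
        history.append((it, cost))
        last_step = step
        if rel < config.tolerance:
            converged = True
            break
    return W, history, converged, rho0, rho


def _sgd(
    X: np.ndarray,
    labels: np.ndarray,
    W0: np.ndarray,
    sigma: float,
    config: FitConfig,
) -> tuple[np.ndarray, list[tuple[int, float]], bool, float, float]:
    """Minibatch stochastic gradient on the CKA cost.

    Each minibatch contributes the gradient of the cost computed on its own
    sub-kernel. The full-batch cost is recorded once per epoch; no
    monotonicity is guaranteed on this path.
    """
    rng = np.random.default_rng(config.seed)
    Klc_full = center_kernel(label_kernel(labels))
    n = X.shape[0]
    W = W0.copy()
    cost0, _, rho0 = cka_cost_and_gradient(W, X, Klc_full, sigma)
    history = [(0, cost0)]
    lr = config.learning_rate
    rho = rho0
    for epoch in range(1, config.max_iters + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if np.unique(labels[idx]).size < 2 or idx.size < 3:
                continue
            Klc_b = center_kernel(label_kernel(labels[idx]))
            try:
                _, g, _ = cka_cost_and_gradient(W, X[idx], Klc_b, sigma)
            except Exception:
                continue
            W = W - lr * g
        cost, _, rho = cka_cost_and_gradient(W, X, Klc_full, sigma)
        history.append((epoch, cost))
        lr = config.learning_rate / (1.0 + 0.1 * epoch)  # standard decay
    return W, history, False, rho0, rho


def fit_metric(
    data: FeatureMatrix,
    config: FitConfig | None = None,
    W0: np.ndarray | None = None,
    sigma: float | None = None,
) -> MetricModel:
    """Fit the CKA-optimal projection and bandwidth on labeled data.

    Pipeline: z-score features; principal-component initialization of W
    (unless ``W0`` is given); bandwidth tuned once on the initialized
    projection (unless ``sigma`` is given); then gradient descent on -log rho_hat (full-batch with
    backtracking by default, minibatch SGD if ``config.batch_size`` is set).
    The final full-batch alignment is never below the initialization's on
    the default path.
    """
    config = config or FitConfig()
    data.require_supervised()
    if data.n_samples < data.n_classes + 1:
        raise ParameterError("need at least C + 1 samples to fit")
    Xs, mean, scale = _standardize_fit(data.values)
    d = config.d if config.d is not None else min(data.n_features, 3 * data.n_classes)
    if W0 is None:
        W0 = pca_init(Xs, d)
    else:
        W0 = np.asarray(W0, dtype=float)
        if W0.shape[0] != data.n_features:
            raise ShapeError("W0 row count must equal the feature count")
        d = W0.shape[1]
    if sigma is None:
        sigma = tune_bandwidth(Xs, W0, strategy=config.bandwidth_strategy)
    elif sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    Klc = center_kernel(label_kernel(data.labels))
    if config.batch_size is None:
        W, history, converged, rho0, rho = _descend(
            lambda w: cka_cost_and_gradient(w, Xs, Klc, sigma), W0, config
        )
    else:
        W, history, converged, rho0, rho = _sgd(Xs, data.labels, W0, sigma, config)
    return MetricModel(
        W=W,
        sigma=float(sigma),
        d=d,
        mean_=mean,
        scale_=scale,
        fit_history=history,
        seed=config.seed,
        converged=converged,
        rho_init=rho0,
        rho_final=rho,
    )


def transform(X: np.ndarray, model: MetricModel) -> np.ndarray:
    """Apply the learned map: standardize, then project, Y = X_std @ W.

    Euclidean distances in Y equal the learned generalized Euclidean
    distances in the standardized input space.
    """
    return model.standardize(X) @ model.W
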