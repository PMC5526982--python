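"""Layer-wise CKA pretraining of feed-forward networks.

The linear metric y = xW is the single-layer, linear-activation special
case of an M-layer feed-forward map

    h^m = theta(b^m + h^{m-1} W^m),    h^0 = x,

with the saturating sigmoid theta(z) = (tanh(z) + 1)/2 on hidden layers.
Each hidden projection W^m is pretrained sequentially — earlier layers are
frozen once fitted — by maximizing the alignment between the Gaussian
kernel on that layer's representation H^m = theta(H^{m-1} W^m) (offsets are
held at zero during pretraining) and the class-indicator kernel. The
pretrained stack initializes a network that is then fine-tuned by
backpropagation on cross-entropy (see :mod:`ckalign.classifiers`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FeatureMatrix
from .exceptions import ParameterError, ShapeError
from .kernels import (
    center_kernel,
    cost_and_kernel_gradient,
    distance_laplacian,
    label_kernel,
    projected_gaussian_kernel,
)
from .metric import FitConfig, _descend, _standardize_fit, pca_init, tune_bandwidth

__all__ = [
    "NetworkStack",
    "sigmoid",
    "sigmoid_grad",
    "layer_forward",
    "layer_kernel",
    "saturated_cost_and_gradient",
    "pretrain_network",
    "random_stack",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Saturating transfer theta(z) = (tanh(z) + 1)/2, range (0, 1)."""
    return (np.tanh(z) + 1.0) / 2.0


def sigmoid_grad(z: np.ndarray) -> np.ndarray:
    """theta'(z) = (1 - tanh^2 z)/2."""
    t = np.tanh(z)
    return (1.0 - t * t) / 2.0


@dataclass
class NetworkStack:
    """Ordered layer parameters of a feed-forward classifier.

    ``layers`` holds (W^m, b^m) pairs chaining sizes[0]=P through
    sizes[-1]=C; hidden layers use the sigmoid transfer, the output layer
    a softmax (applied by the classifier, not stored here). Standardization
    of the raw inputs is stored so the stack is self-contained.
    """

    layers: list[tuple[np.ndarray, np.ndarray]]
    sizes: tuple[int, ...]
    activation: str = "sigmoid"
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None
    fit_histories: list[list[tuple[int, float]]] = field(default_factory=list)
    layer_sigmas: list[float] = field(default_factory=list)
    layer_alignments: list[float] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for m, (W, b) in enumerate(self.layers):
            if W.shape != (self.sizes[m], self.sizes[m + 1]):
                raise ShapeError(
                    f"layer {m}: W shape {W.shape} breaks chain "
                    f"{self.sizes[m]}→{self.sizes[m + 1]}"
                )
            if b.shape != (self.sizes[m + 1],):
                raise ShapeError(f"layer {m}: offset shape {b.shape} invalid")
        if self.activation not in ("sigmoid", "identity"):
            raise ParameterError(f"unknown activation {self.activation!r}")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.mean_ is None:
            return X
        return (X - self.mean_) / self.scale_

    def hidden_representations(self, X: np.ndarray) -> list[np.ndarray]:
        """H^1 .. H^{M-1} (all layers except the softmax output layer)."""
        H = self.standardize(X)
        out = []
        for W, b in self.layers[:-1]:
            H = layer_forward(H, W, b, saturate=self.activation == "sigmoid")
            out.append(H)
        return out


def layer_forward(
    H_prev: np.ndarray, W: np.ndarray, b: np.ndarray, saturate: bool = True
) -> np.ndarray:
    """One layer: theta(b + H_prev @ W), or the affine map if not saturating."""
    H_prev = np.asarray(H_prev, dtype=float)
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if H_prev.ndim != 2 or H_prev.shape[1] != W.shape[0] or b.shape != (W.shape[1],):
        raise ShapeError(
            f"shape chain broken: H {H_prev.shape}, W {W.shape}, b {b.shape}"
        )
    Z = b + H_prev @ W
    return sigmoid(Z) if saturate else Z


def layer_kernel(H: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel on the Euclidean distances among layer representations.

    Identical to the projected Gaussian kernel with the identity projection.
    """
    return projected_gaussian_kernel(H, None, sigma)


def saturated_cost_and_gradient(
    W: np.ndarray,
    H_prev: np.ndarray,
    Kl_centered: np.ndarray,
    sigma: float,
) -> tuple[float, np.ndarray, float]:
    """-log rho_hat of the kernel on theta(H_prev W), gradient via the chain rule.

    With L the distance Laplacian of the kernel-space gradient,
    d cost/dH = (-2/sigma^2) L H, and the sigmoid backprop gives
    grad = H_prev^T (dcost/dH ∘ theta'(Z)).
    """
    Z = np.asarray(H_prev, dtype=float) @ np.asarray(W, dtype=float)
    H = sigmoid(Z)
    K = layer_kernel(H, sigma)
    cost, G, rho = cost_and_kernel_gradient(K, Kl_centered)
    L = distance_laplacian(G, K)
    dH = (-2.0 / sigma**2) * (L @ H)
    grad = H_prev.T @ (dH * sigmoid_grad(Z))
    return cost, grad, rho


def _layer_init(H_prev: np.ndarray, q: int, rng: np.random.Generator) -> np.ndarray:
    """PCA of the previous representation, padded with small random columns
    when the requested width exceeds the available rank."""
    n, p = H_prev.shape
    d_pca = min(q, p, n - 1)
    W = pca_init(H_prev, d_pca)
    if d_pca < q:
        pad = rng.normal(scale=0.1, size=(p, q - d_pca))
        W = np.hstack([W, pad])
    return W


def pretrain_network(
    data: FeatureMatrix,
    sizes: tuple[int, ...],
    config: FitConfig | None = None,
    activation: str = "sigmoid",
) -> NetworkStack:
    """Sequentially pretrain hidden projections by CKA maximization.

    ``sizes`` chains from P to C, e.g. (P, m1, m2, C). For each hidden layer
    m = 1..M-1 in order: initialize W^m from the PCA of H^{m-1}, tune the
    bandwidth on the initialized saturated representation, maximize
    rho_hat(K̄_m, K̄_L) by full-batch descent, freeze, and move up. Offsets
    stay zero during pretraining. The output layer is randomly initialized
    (it is trained only during fine-tuning).

    With ``activation="identity"`` and a single hidden layer this is
    exactly the linear metric fit.
    """
    config = config or FitConfig()
    data.require_supervised()
    sizes = tuple(int(s) for s in sizes)
    if len(sizes) < 2:
        raise ParameterError("sizes must chain at least input → output")
    if sizes[0] != data.n_features:
        raise ShapeError(
            f"sizes[0]={sizes[0]} must equal the feature count {data.n_features}"
        )
    rng = np.random.default_rng(config.seed)
    Xs, mean, scale = _standardize_fit(data.values)
    Klc = center_kernel(label_kernel(data.labels))
    saturate = activation == "sigmoid"

    layers: list[tuple[np.ndarray, np.ndarray]] = []
    histories: list[list[tuple[int, float]]] = []
    sigmas: list[float] = []
    alignments: list[float] = []
    H = Xs
    for m in range(len(sizes) - 2):
        q = sizes[m + 1]
        W0 = _layer_init(H, q, rng)
        if saturate:
            sigma = tune_bandwidth(sigmoid(H @ W0), None, config.bandwidth_strategy)
            obj = lambda w: saturated_cost_and_gradient(w, H, Klc, sigma)  # noqa: E731
        else:
            sigma = tune_bandwidth(H, W0, config.bandwidth_strategy)
            from .kernels import cka_cost_and_gradient

            obj = lambda w: cka_cost_and_gradient(w, H, Klc, sigma)  # noqa: E731
        W, history, _, _, rho = _descend(obj, W0, config)
        layers.append((W, np.zeros(q)))
        histories.append(history)
        sigmas.append(float(sigma))
        alignments.append(rho)
        H = sigmoid(H @ W) if saturate else H @ W

    # Output layer: small random init, trained only during fine-tuning.
    q_out = sizes[-1]
    W_out = rng.normal(scale=0.1, size=(sizes[-2], q_out))
    layers.append((W_out, np.zeros(q_out)))

    return NetworkStack(
        layers=layers,
        sizes=sizes,
        activation=activation,
        mean_=mean,
        scale_=scale,
        fit_histories=histories,
        layer_sigmas=sigmas,
        layer_alignments=alignments,
        seed=config.seed,
    )


def random_stack(
    n_features: int,
    sizes: tuple[int, ...],
    seed: int = 0,
) -> NetworkStack:
    """Randomly initialized stack of the same shape, for baseline comparisons.

    Glorot-style scaling; standardization left to the caller (``mean_``
    unset means inputs pass through untouched).
    """
    sizes = tuple(int(s) for s in sizes)
    if sizes[0] != n_features:
        raise ShapeError("sizes[0] must equal the feature count")
    rng = np.random.default_rng(seed)
    layers = []
    for q_in, q_out in zip(sizes[:-1], sizes[1:]):
        W = rng.normal(scale=np.sqrt(2.0 / (q_in + q_out)), size=(q_in, q_out))
        layers.append((W, np.zeros(q_out)))
    return NetworkStack(layers=layers, sizes=sizes, seed=seed)
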