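"""Downstream classifiers consuming the learned metric or pretrained stack.

Three families, mirroring a typical computer-aided-diagnosis comparison:

* k-nn with k in {1, 3, 5, 7, 9}, majority vote under Euclidean distance in
  the (optionally metric-transformed) space; vote ties broken by smallest
  summed distance, then smallest class index.
* soft-margin SVM with C in {0.1, 1, 10, 100, 1000} on a precomputed
  Gaussian kernel (the projected kernel when a metric model is supplied),
  one-vs-one for multi-class (sklearn's SMO-based SVC).
* feed-forward NN with sigmoid hidden layers and softmax output, fine-tuned
  by gradient descent on cross-entropy; initialized either randomly or from
  a CKA-pretrained stack.

Hyperparameters are selected by subject-grouped cross-validation: all scans
of one subject stay in a single fold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .data import FeatureMatrix
from .exceptions import (
    GroupingViolationError,
    OptimizationError,
    ParameterError,
    ShapeError,
)
from .kernels import projected_gaussian_kernel
from .metric import MetricModel, transform, tune_bandwidth
from .pretrain import NetworkStack, sigmoid, sigmoid_grad

__all__ = [
    "KNN_GRID",
    "SVM_GRID",
    "knn_classify",
    "svm_classify",
    "nn_predict_proba",
    "nn_predict",
    "nn_finetune",
    "make_subject_folds",
    "grid_search",
    "layer_size_grid",
]

KNN_GRID = (1, 3, 5, 7, 9)
SVM_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)


def _space(data_values: np.ndarray, model: MetricModel | None) -> np.ndarray:
    return data_values if model is None else transform(data_values, model)


def knn_classify(
    train: FeatureMatrix,
    test_values: np.ndarray,
    k: int,
    model: MetricModel | None = None,
) -> np.ndarray:
    """k-nearest-neighbor majority vote, optionally in the learned space.

    Ties (equal vote counts) go to the class with the smallest summed
    neighbor distance; any residual tie to the smallest class index in
    sorted label order.
    """
    if k <= 0 or k % 2 == 0:
        raise ParameterError(f"k must be odd and positive, got {k}")
    if k > train.n_samples:
        raise ParameterError(f"k={k} exceeds {train.n_samples} training samples")
    Xtr = _space(train.values, model)
    Xte = _space(np.asarray(test_values, dtype=float), model)
    classes = train.classes
    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_index[c] for c in train.labels])
    D = cdist(Xte, Xtr)
    nearest = np.argsort(D, axis=1, kind="stable")[:, :k]
    out = np.empty(Xte.shape[0], dtype=classes.dtype)
    for i in range(Xte.shape[0]):
        nb = nearest[i]
        votes = np.bincount(y_idx[nb], minlength=classes.size)
        top = votes.max()
        tied = np.flatnonzero(votes == top)
        if tied.size == 1:
            out[i] = classes[tied[0]]
            continue
        sums = []
        for c in tied:
            mask = y_idx[nb] == c
            sums.append(D[i, nb[mask]].sum())
        out[i] = classes[tied[int(np.argmin(sums))]]  # argmin ties → smallest index
    return out


def svm_classify(
    train: FeatureMatrix,
    test_values: np.ndarray,
    C: float,
    model: MetricModel | None = None,
    sigma: float | None = None,
) -> np.ndarray:
    """Soft-margin SVM on a precomputed Gaussian kernel.

    With a metric model, the kernel is the projected Gaussian kernel with
    the learned W and sigma; without one, a plain Gaussian kernel on the
    raw features with a median-heuristic bandwidth (overridable). One-vs-one
    multi-class reduction.
    """
    if C <= 0:
        raise ParameterError(f"C must be positive, got {C}")
    Xte = np.asarray(test_values, dtype=float)
    if model is not None:
        Ytr = transform(train.values, model)
        Yte = transform(Xte, model)
        s = model.sigma
    else:
        Ytr, Yte = train.values, Xte
        s = sigma if sigma is not None else tune_bandwidth(Ytr)
    Ktr = projected_gaussian_kernel(Ytr, None, s)
    D2 = cdist(Yte, Ytr, metric="sqeuclidean")
    Kte = np.exp(-D2 / (2.0 * s**2))
    clf = SVC(C=C, kernel="precomputed")
    clf.fit(Ktr, train.labels)
    return clf.predict(Kte)


def _forward_full(stack: NetworkStack, X: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """All pre-activations Z and activations H through the stack (softmax last)."""
    H = stack.standardize(X)
    Zs, Hs = [], [H]
    for m, (W, b) in enumerate(stack.layers):
        Z = b + Hs[-1] @ W
        Zs.append(Z)
        if m < stack.n_layers - 1:
            Hs.append(sigmoid(Z) if stack.activation == "sigmoid" else Z)
        else:
            Zm = Z - Z.max(axis=1, keepdims=True)
            E = np.exp(Zm)
            Hs.append(E / E.sum(axis=1, keepdims=True))
    return Zs, Hs


def nn_predict_proba(stack: NetworkStack, X: np.ndarray) -> np.ndarray:
    """Softmax class probabilities; rows sum to 1."""
    _, Hs = _forward_full(stack, np.asarray(X, dtype=float))
    return Hs[-1]


def nn_predict(stack: NetworkStack, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    P = nn_predict_proba(stack, X)
    return np.asarray(classes)[np.argmax(P, axis=1)]


def _one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for n, l in enumerate(labels):
        Y[n, idx[l]] = 1.0
    return Y


def cross_entropy(stack: NetworkStack, X: np.ndarray, Y: np.ndarray) -> float:
    """Mean cross-entropy of softmax outputs against one-hot targets."""
    P = nn_predict_proba(stack, X)
    return float(-np.mean(np.sum(Y * np.log(np.clip(P, 1e-12, None)), axis=1)))


def nn_gradients(
    stack: NetworkStack, X: np.ndarray, Y: np.ndarray
) -> tuple[float, list[tuple[np.ndarray, np.ndarray]]]:
    """Backpropagated cross-entropy gradients for every (W, b)."""
    n = X.shape[0]
    Zs, Hs = _forward_full(stack, X)
    loss = float(-np.mean(np.sum(Y * np.log(np.clip(Hs[-1], 1e-12, None)), axis=1)))
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * stack.n_layers  # type: ignore
    delta = (Hs[-1] - Y) / n  # softmax + cross-entropy
    for m in range(stack.n_layers - 1, -1, -1):
        gW = Hs[m].T @ delta
        gb = delta.sum(axis=0)
        grads[m] = (gW, gb)
        if m > 0:
            delta = delta @ stack.layers[m][0].T
            if stack.activation == "sigmoid":
                delta = delta * sigmoid_grad(Zs[m - 1])
    return loss, grads


def nn_finetune(
    train: FeatureMatrix,
    stack: NetworkStack,
    epochs: int = 200,
    learning_rate: float = 0.5,
    momentum: float = 0.9,
    seed: int = 0,
) -> tuple[NetworkStack, list[float]]:
    """Fine-tune all weights and offsets by gradient descent on cross-entropy.

    Full-batch descent with momentum; the loss trajectory is returned
    alongside the updated stack. Non-finite loss aborts with diagnostics.
    The stack must chain to C = number of classes in ``train``.
    """
    classes = train.classes
    if stack.sizes[-1] != classes.size:
        raise ShapeError(
            f"output width {stack.sizes[-1]} != {classes.size} classes"
        )
    if stack.mean_ is None:
        # Random stacks carry no standardization; adopt the training split's.
        from .metric import _standardize_fit

        _, mean, scale = _standardize_fit(train.values)
        stack = replace(stack, mean_=mean, scale_=scale)
    X = train.values
    Y = _one_hot(train.labels, classes)
    layers = [(W.copy(), b.copy()) for W, b in stack.layers]
    work = replace(stack, layers=layers)
    vel = [(np.zeros_like(W), np.zeros_like(b)) for W, b in layers]
    losses = []
    for epoch in range(epochs):
        loss, grads = nn_gradients(work, X, Y)
        if not np.isfinite(loss):
            raise OptimizationError(
                f"non-finite training loss at epoch {epoch} "
                f"(lr={learning_rate}, momentum={momentum})"
            )
        losses.append(loss)
        for m in range(work.n_layers):
            vW, vb = vel[m]
            gW, gb = grads[m]
            vW = momentum * vW - learning_rate * gW
            vb = momentum * vb - learning_rate * gb
            vel[m] = (vW, vb)
            W, b = work.layers[m]
            work.layers[m] = (W + vW, b + vb)
            if not (np.all(np.isfinite(work.layers[m][0]))
                    and np.all(np.isfinite(work.layers[m][1]))):
                raise OptimizationError(
                    f"non-finite weights in layer {m} at epoch {epoch} "
                    f"(lr={learning_rate}, momentum={momentum})"
                )
    losses.append(cross_entropy(work, X, Y))
    return work, losses


def make_subject_folds(
    subjects: np.ndarray, labels: np.ndarray, n_folds: int = 5, seed: int = 0
) -> np.ndarray:
    """Deterministic subject-grouped, class-balanced fold assignment.

    Subjects are shuffled (seeded), grouped by their class, and dealt
    round-robin to folds within each class so every fold sees every class.
    Returns a per-sample fold id; all samples of a subject share an id.
    """
    subjects = np.asarray(subjects)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    subj_class: dict = {}
    for s, l in zip(subjects, labels):
        subj_class.setdefault(s, l)
    uniq = sorted(subj_class.keys(), key=str)
    order = rng.permutation(len(uniq))
    fold_of: dict = {}
    counters: dict = {}
    for i in order:
        s = uniq[i]
        c = subj_class[s]
        k = counters.get(c, 0)
        fold_of[s] = k % n_folds
        counters[c] = k + 1
    return np.array([fold_of[s] for s in subjects])


def _validate_folds(subjects: np.ndarray, folds: np.ndarray, labels: np.ndarray) -> None:
    df = pd.DataFrame({"subject": subjects, "fold": folds, "label": labels})
    spans = df.groupby("subject")["fold"].nunique()
    bad = spans[spans > 1]
    if len(bad):
        raise GroupingViolationError(
            f"subjects spanning folds: {list(bad.index[:5])}"
        )
    n_classes = df["label"].nunique()
    per_fold = df.groupby("fold")["label"].nunique()
    if (per_fold < n_classes).any():
        raise GroupingViolationError("a fold is missing at least one class")


@dataclass
class GridResult:
    """Selected hyperparameter and the full cross-validation table."""

    best: object
    best_accuracy: float
    table: pd.DataFrame


def layer_size_grid(n_classes: int, n_features: int, n_points: int = 4) -> list[int]:
    """Log-spaced hidden-layer sizes in [C, P-1]."""
    lo, hi = n_classes, max(n_features - 1, n_classes)
    sizes = np.unique(
        np.round(np.exp(np.linspace(np.log(lo), np.log(hi), n_points))).astype(int)
    )
    return [int(s) for s in sizes]


def grid_search(
    family: str,
    grid: list,
    train: FeatureMatrix,
    folds: np.ndarray,
    model: MetricModel | None = None,
    pretrained: bool = False,
    nn_layers: int = 1,
    nn_epochs: int = 150,
    seed: int = 0,
    fit_config=None,
) -> GridResult:
    """Subject-grouped cross-validated hyperparameter selection.

    ``grid`` holds k values (knn), C values (svm), or hidden-layer sizes
    (nn). Accuracy is scored per sample within subject-grouped folds; the
    best mean accuracy wins, ties broken toward the simpler model (smaller
    grid value — grids are evaluated in ascending order and strict
    improvement is required to switch).

    For family "nn", each grid point trains a network with ``nn_layers``
    hidden layers of that size, initialized randomly or (``pretrained``)
    by per-fold CKA pretraining. For "knn"/"svm" a metric ``model`` (fit on
    the full training split) is applied if given.
    """
    if not grid:
        raise ParameterError("hyperparameter grid is empty")
    if train.subjects is None:
        raise ParameterError("grid search requires subject identifiers")
    folds = np.asarray(folds)
    _validate_folds(train.subjects, folds, train.labels)
    fold_ids = np.unique(folds)
    grid = sorted(grid)
    rows = []
    for g in grid:
        accs = []
        for f in fold_ids:
            tr = train.subset(folds != f)
            va = train.subset(folds == f)
            if family == "knn":
                pred = knn_classify(tr, va.values, int(g), model=model)
            elif family == "svm":
                pred = svm_classify(tr, va.values, float(g), model=model)
            elif family == "nn":
                C = train.n_classes
                sizes = (train.n_features, *([int(g)] * nn_layers), C)
                if pretrained:
                    from .metric import FitConfig

                    cfg = fit_config or FitConfig(seed=seed)
                    stack = pretrain_network_cached(tr, sizes, cfg)
                else:
                    stack = random_stack_for(tr, sizes, seed)
                stack, _ = nn_finetune(tr, stack, epochs=nn_epochs, seed=seed)
                pred = nn_predict(stack, va.values, tr.classes)
            else:
                raise ParameterError(f"unknown family {family!r}")
            accs.append(float(np.mean(pred == va.labels)))
        rows.append({"param": g, "mean_accuracy": float(np.mean(accs)),
                     **{f"fold{int(f)}": a for f, a in zip(fold_ids, accs)}})
    table = pd.DataFrame(rows)
    best_i = 0
    for i in range(1, len(grid)):  # ascending grid ⇒ ties keep the simpler model
        if rows[i]["mean_accuracy"] > rows[best_i]["mean_accuracy"]:
            best_i = i
    return GridResult(best=grid[best_i], best_accuracy=rows[best_i]["mean_accuracy"], table=table)


def pretrain_network_cached(tr: FeatureMatrix, sizes, cfg):
    from .pretrain import pretrain_network

    return pretrain_network(tr, sizes, cfg)


def random_stack_for(tr: FeatureMatrix, sizes, seed: int) -> NetworkStack:
    from .pretrain import random_stack

    return random_stack(tr.n_features, sizes, seed=seed)
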