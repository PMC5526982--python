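"""k-nn, kernel SVM, NN fine-tuning, and subject-grouped grid search."""

import numpy as np
import pytest

from ckalign import (
    FeatureMatrix,
    FitConfig,
    fit_metric,
    grid_search,
    knn_classify,
    make_subject_folds,
    nn_finetune,
    nn_predict,
    nn_predict_proba,
    pretrain_network,
    random_stack,
    svm_classify,
    transform,
)
from ckalign.classifiers import layer_size_grid
from ckalign.exceptions import (
    GroupingViolationError,
    OptimizationError,
    ParameterError,
)
from ckalign.metric import MetricModel

from test_kernels import finite_difference_gradient


def brute_force_knn(Xtr, ytr, Xte, k):
    """Exhaustive all-pairs scan with the documented tie-break."""
    classes = np.unique(ytr)
    preds = []
    for x in Xte:
        d = np.sqrt(((Xtr - x) ** 2).sum(axis=1))
        nb = np.argsort(d, kind="stable")[:k]
        best, best_key = None, None
        for c in classes:
            mask = ytr[nb] == c
            count = mask.sum()
            sumd = d[nb[mask]].sum() if count else np.inf
            key = (-count, sumd)  # more votes, then smaller summed distance,
            if best_key is None or key < best_key:  # then smaller class index
                best, best_key = c, key
        preds.append(best)
    return np.array(preds)


class TestKnn:
    def test_k1_returns_exact_neighbor_label(self, tiny3class):
        data, _ = tiny3class
        pred = knn_classify(data, data.values[:5], 1)
        np.testing.assert_array_equal(pred, data.labels[:5])

    def test_matches_exhaustive_oracle(self, rng):
        Xtr = rng.normal(size=(30, 4))
        ytr = rng.integers(0, 3, size=30)
        ytr[:3] = [0, 1, 2]
        Xte = rng.normal(size=(12, 4))
        train = FeatureMatrix(Xtr, ytr)
        for k in (1, 3, 5):
            np.testing.assert_array_equal(
                knn_classify(train, Xte, k), brute_force_knn(Xtr, ytr, Xte, k)
            )

    def test_metric_zeroing_noise_gives_perfect_split(self):
        # disjoint class supports on the relevant axis, buried in scaled noise
        from ckalign import generate
        from ckalign.simulate import GeneratorSpec

        spec = GeneratorSpec(
            n_subjects=(20, 20), scans_per_subject=(2, 2), p_signal=1,
            class_separation=20.0, between_subject_sd=0.5, within_subject_sd=0.3,
            feature_blocks=(("nuisance", 9, 0.0, 100.0),), seed=5,
        )
        data, _ = generate(spec)
        model = fit_metric(data, FitConfig(seed=0, max_iters=80))
        test, _ = generate(GeneratorSpec(**{**spec.__dict__, "seed": 6}))
        pred = knn_classify(data, test.values, 5, model=model)
        assert np.mean(pred == test.labels) == 1.0

    def test_metric_equivalence(self, tiny3class):
        # classify on transform(X) with no model == classify on X with model
        data, _ = tiny3class
        model = fit_metric(data, FitConfig(seed=1, max_iters=30))
        plain = FeatureMatrix(transform(data.values, model), data.labels)
        p1 = knn_classify(data, data.values, 3, model=model)
        p2 = knn_classify(plain, transform(data.values, model), 3)
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("k", [2, 0, 31])
    def test_invalid_k(self, tiny3class, k):
        data, _ = tiny3class
        with pytest.raises(ParameterError):
            knn_classify(data, data.values, k)


class TestSvm:
    def test_separable_toy_zero_training_error(self, rng):
        X = np.vstack([rng.normal(size=(10, 2)) - 5, rng.normal(size=(10, 2)) + 5])
        y = np.array([0] * 10 + [1] * 10)
        train = FeatureMatrix(X, y)
        pred = svm_classify(train, X, C=10.0)
        np.testing.assert_array_equal(pred, y)

    def test_precomputed_equals_transformed_euclidean(self, tiny3class):
        data, _ = tiny3class
        model = fit_metric(data, FitConfig(seed=2, max_iters=30))
        p1 = svm_classify(data, data.values, 10.0, model=model)
        plain = FeatureMatrix(transform(data.values, model), data.labels)
        p2 = svm_classify(plain, transform(data.values, model), 10.0, sigma=model.sigma)
        np.testing.assert_array_equal(p1, p2)

    def test_invalid_C(self, tiny3class):
        data, _ = tiny3class
        with pytest.raises(ParameterError):
            svm_classify(data, data.values, C=0.0)


class TestNeuralNet:
    def test_softmax_rows_sum_to_one(self, tiny3class, rng):
        data, _ = tiny3class
        stack = random_stack(6, (6, 4, 3), seed=0)
        P = nn_predict_proba(stack, data.values)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= 0)

    def test_cross_entropy_gradient_matches_finite_differences(self):
        from ckalign.classifiers import _one_hot, nn_gradients
        from dataclasses import replace

        r = np.random.default_rng(3)
        X = r.normal(size=(6, 3))
        y = np.array([0, 1, 2, 0, 1, 2])
        stack = random_stack(3, (3, 4, 3), seed=3)
        Y = _one_hot(y, np.array([0, 1, 2]))
        _, grads = nn_gradients(stack, X, Y)
        for m in range(stack.n_layers):
            W = stack.layers[m][0]

            def loss_at(Wm):
                layers = [(w.copy(), b.copy()) for w, b in stack.layers]
                layers[m] = (Wm, layers[m][1])
                from ckalign.classifiers import cross_entropy

                return cross_entropy(replace(stack, layers=layers), X, Y)

            fd = finite_difference_gradient(loss_at, W.copy())
            np.testing.assert_allclose(grads[m][0], fd, rtol=1e-4, atol=1e-8)

    def test_loss_non_increasing_with_suitable_rate(self, tiny3class):
        data, _ = tiny3class
        stack = random_stack(6, (6, 4, 3), seed=4)
        _, losses = nn_finetune(data, stack, epochs=60, learning_rate=0.05,
                                momentum=0.0, seed=4)
        assert all(l2 <= l1 + 1e-10 for l1, l2 in zip(losses, losses[1:]))

    def test_non_finite_loss_raises_with_diagnostics(self, tiny3class):
        data, _ = tiny3class
        stack = random_stack(6, (6, 4, 3), seed=5)
        stack.layers[0] = (stack.layers[0][0] * np.inf, stack.layers[0][1])
        with pytest.raises(OptimizationError, match="lr="):
            nn_finetune(data, stack, epochs=5, seed=5)

    def test_pretrained_init_reaches_low_loss(self, xor2class):
        data, _ = xor2class
        stack = pretrain_network(data, (4, 8, 8, 2), FitConfig(seed=6, max_iters=120))
        tuned, losses = nn_finetune(data, stack, epochs=120, seed=6)
        assert losses[-1] < 0.2
        pred = nn_predict(tuned, data.values, data.classes)
        assert np.mean(pred == data.labels) > 0.9


class TestGridSearch:
    def test_fold_maker_partitions_subjects_with_all_classes(self, tiny3class):
        data, _ = tiny3class
        folds = make_subject_folds(data.subjects, data.labels, n_folds=5, seed=0)
        import pandas as pd

        df = pd.DataFrame({"s": data.subjects, "f": folds, "l": data.labels})
        assert (df.groupby("s")["f"].nunique() == 1).all()
        assert (df.groupby("f")["l"].nunique() == data.n_classes).all()

    def test_single_point_grid(self, tiny3class):
        data, _ = tiny3class
        folds = make_subject_folds(data.subjects, data.labels, 5, seed=0)
        gr = grid_search("knn", [3], data, folds)
        assert gr.best == 3
        assert 0.0 <= gr.best_accuracy <= 1.0
        assert len(gr.table) == 1

    def test_subject_spanning_folds_raises(self, tiny3class):
        data, _ = tiny3class
        folds = make_subject_folds(data.subjects, data.labels, 5, seed=0)
        bad = folds.copy()
        bad[0] = (bad[0] + 1) % 5  # detach one scan from its subject's fold
        with pytest.raises(GroupingViolationError):
            grid_search("knn", [1, 3], data, bad)

    def test_label_noise_prefers_smoother_k(self):
        # two overlapping classes with flipped labels: k=1 overfits the noise
        rng = np.random.default_rng(42)
        n = 120
        X = np.vstack([rng.normal(-0.7, 1.0, size=(n // 2, 2)),
                       rng.normal(0.7, 1.0, size=(n // 2, 2))])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        flip = rng.choice(n, size=n // 6, replace=False)
        y[flip] = 1 - y[flip]
        subjects = np.arange(n)
        data = FeatureMatrix(X, y, subjects=subjects)
        folds = make_subject_folds(subjects, y, 5, seed=1)
        gr = grid_search("knn", [1, 3, 5, 7, 9], data, folds)
        assert gr.best > 1

    def test_reproducible_tables(self, tiny3class):
        data, _ = tiny3class
        folds = make_subject_folds(data.subjects, data.labels, 5, seed=2)
        t1 = grid_search("svm", [1.0, 10.0], data, folds).table
        t2 = grid_search("svm", [1.0, 10.0], data, folds).table
        assert t1.equals(t2)

    def test_layer_size_grid_bounds(self):
        grid = layer_size_grid(3, 310)
        assert grid[0] == 3 and grid[-1] == 309
        assert all(3 <= g <= 309 for g in grid)
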