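"""End-to-end orchestration: simulate/load → fit → classify → evaluate.

One :class:`RunConfig` drives a full study: a subject-grouped 70/30
train/test split, hyperparameter grid search on the training split
(subject-grouped 5-fold CV), and final test-set scoring with bootstrap
confidence intervals — for the baseline and the CKA-enhanced variant of
each requested classifier family. All randomness fans out from one global
seed through :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classifiers import (
    KNN_GRID,
    SVM_GRID,
    grid_search,
    knn_classify,
    layer_size_grid,
    make_subject_folds,
    nn_finetune,
    nn_predict,
    nn_predict_proba,
    svm_classify,
)
from .data import FeatureMatrix
from .evaluation import (
    EvalReport,
    bootstrap_ci,
    per_class_auc,
    report_table,
    score,
    std_tau,
)
from .exceptions import GroupingViolationError, ParameterError
from .metric import FitConfig, fit_metric
from .pretrain import pretrain_network, random_stack
from .simulate import GeneratorSpec, generate

logger = logging.getLogger("ckalign")

__all__ = ["RunConfig", "subject_split", "run_pipeline", "PipelineResult"]


@dataclass
class RunConfig:
    """Study configuration.

    Either ``data`` (an in-memory table) or ``generator`` (a synthetic
    spec) provides the input. ``families`` selects classifiers from
    {"knn", "svm", "nn1", "nn2"} (the digit = hidden layers); each runs as
    a baseline and, when ``with_metric`` is on, as a CKA-enhanced variant
    (metric transform for knn/svm, layer-wise pretraining for nn).
    """

    data: FeatureMatrix | None = None
    generator: GeneratorSpec | None = None
    families: tuple[str, ...] = ("knn", "svm", "nn1")
    with_metric: bool = True
    with_baseline: bool = True
    test_fraction: float = 0.3
    n_folds: int = 5
    fit: FitConfig = field(default_factory=FitConfig)
    nn_grid: list[int] | None = None  # hidden sizes; None → log-spaced [C, P-1]
    nn_epochs: int = 200
    bootstrap_resamples: int = 1000
    seed: int = 0
    output_dir: str | Path | None = None

    def resolve_data(self) -> FeatureMatrix:
        if self.data is not None:
            return self.data
        if self.generator is not None:
            data, _ = generate(self.generator)
            return data
        raise ParameterError("RunConfig needs either data or a generator")


@dataclass
class PipelineResult:
    reports: list[EvalReport]
    table: "object"
    predictions: dict
    models: dict
    grid_tables: dict
    seeds: dict


def subject_split(
    data: FeatureMatrix, test_fraction: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified subject-level holdout: boolean train/test masks.

    Every scan of a subject lands on one side of the split; each class
    contributes ~``test_fraction`` of its subjects to the test side.
    """
    if data.subjects is None:
        raise ParameterError("subject identifiers are required for splitting")
    rng = np.random.default_rng(seed)
    subj_class: dict = {}
    for s, l in zip(data.subjects, data.labels):
        if s in subj_class and subj_class[s] != l:
            raise GroupingViolationError(f"subject {s!r} has multiple labels")
        subj_class[s] = l
    test_subjects = set()
    for c in data.classes:
        subs = sorted((s for s, l in subj_class.items() if l == c), key=str)
        n_test = max(1, int(round(test_fraction * len(subs))))
        if n_test >= len(subs):
            raise ParameterError(f"class {c!r} has too few subjects to split")
        picked = rng.choice(len(subs), size=n_test, replace=False)
        test_subjects.update(subs[i] for i in picked)
    test_mask = np.array([s in test_subjects for s in data.subjects])
    return ~test_mask, test_mask


def _evaluate(
    name: str,
    y_true: np.ndarray,
    y_pred: np.ndarray,
    B: int,
    seed: int,
    proba: np.ndarray | None = None,
    classes: np.ndarray | None = None,
) -> EvalReport:
    acc, tau = score(y_true, y_pred)
    ci: dict = {}
    m, lo, hi = bootstrap_ci(y_true, y_pred, "accuracy", B=B, seed=seed)
    ci["accuracy"] = (lo, hi)
    for c in tau:
        m, lo, hi = bootstrap_ci(y_true, y_pred, ("tau", c), B=B, seed=seed)
        ci[("tau", c)] = (lo, hi)
    auc, auc_mean = ({}, float("nan"))
    if proba is not None:
        auc, auc_mean = per_class_auc(y_true, proba, classes)
    return EvalReport(
        name=name,
        accuracy=acc,
        tau=tau,
        ci=ci,
        std_tau=std_tau(tau),
        auc=auc,
        auc_mean=auc_mean,
        n_resamples=B,
        seed=seed,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full study described by ``config``.

    Returns all evaluation reports plus the formatted table; when
    ``config.output_dir`` is set, writes the table (CSV and text), the
    predictions, the serialized models, and a JSON log of every derived
    seed, so any number in the outputs is regenerable from the log alone.
    """
    data = config.resolve_data()
    data.require_supervised()
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        k: int(s.generate_state(1)[0] % (2**31))
        for k, s in zip(
            ["split", "folds", "fit", "nn", "bootstrap"], ss.spawn(5)
        )
    }
    logger.info("derived stage seeds: %s", seeds)

    train_mask, test_mask = subject_split(data, config.test_fraction, seeds["split"])
    train, test = data.subset(train_mask), data.subset(test_mask)
    folds = make_subject_folds(train.subjects, train.labels, config.n_folds, seeds["folds"])

    model = None
    models: dict = {}
    if config.with_metric and any(f in ("knn", "svm") for f in config.families):
        fit_cfg = FitConfig(**{**config.fit.__dict__, "seed": seeds["fit"]})
        model = fit_metric(train, fit_cfg)
        models["metric"] = model
        logger.info(
            "metric fit: rho %.4f -> %.4f in %d iters",
            model.rho_init, model.rho_final, len(model.fit_history) - 1,
        )

    reports, predictions, grid_tables = [], {}, {}
    C = train.n_classes
    nn_grid = config.nn_grid or layer_size_grid(C, train.n_features)

    def finish(name, pred, proba=None):
        predictions[name] = pred
        reports.append(
            _evaluate(
                name, test.labels, pred, config.bootstrap_resamples,
                seeds["bootstrap"], proba, train.classes,
            )
        )

    for family in config.families:
        variants = []
        if config.with_baseline:
            variants.append(False)
        if config.with_metric:
            variants.append(True)
        for enhanced in variants:
            if family == "knn":
                gm = model if enhanced else None
                gr = grid_search("knn", list(KNN_GRID), train, folds, model=gm)
                name = ("ML + " if enhanced else "") + "k-nn"
                grid_tables[name] = gr.table
                finish(name, knn_classify(train, test.values, int(gr.best), model=gm))
            elif family == "svm":
                gm = model if enhanced else None
                gr = grid_search("svm", list(SVM_GRID), train, folds, model=gm)
                name = ("ML + " if enhanced else "") + "SVM"
                grid_tables[name] = gr.table
                finish(name, svm_classify(train, test.values, float(gr.best), model=gm))
            elif family.startswith("nn"):
                layers = int(family[2:] or 1)
                fit_cfg = FitConfig(**{**config.fit.__dict__, "seed": seeds["fit"]})
                gr = grid_search(
                    "nn", list(nn_grid), train, folds,
                    pretrained=enhanced, nn_layers=layers,
                    nn_epochs=config.nn_epochs, seed=seeds["nn"],
                    fit_config=fit_cfg,
                )
                m = int(gr.best)
                sizes = (train.n_features, *([m] * layers), C)
                if enhanced:
                    stack = pretrain_network(train, sizes, fit_cfg)
                    name = f"Pretrained {layers}-layer NN"
                else:
                    stack = random_stack(train.n_features, sizes, seed=seeds["nn"])
                    name = f"{layers}-layer NN"
                stack, _ = nn_finetune(
                    train, stack, epochs=config.nn_epochs, seed=seeds["nn"]
                )
                grid_tables[name] = gr.table
                models[name] = stack
                finish(
                    name,
                    nn_predict(stack, test.values, train.classes),
                    nn_predict_proba(stack, test.values),
                )
            else:
                raise ParameterError(f"unknown classifier family {family!r}")

    table = report_table(reports)
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import save_model, save_table

        table.to_csv(outdir / "report.csv", index=False)
        (outdir / "report.txt").write_text(table.to_string(index=False) + "\n")
        (outdir / "seeds.json").write_text(json.dumps({"global": config.seed, **seeds}))
        import pandas as pd

        pd.DataFrame(
            {"true": test.labels, **{k: v for k, v in predictions.items()}}
        ).to_csv(outdir / "predictions.csv", index=False)
        for key, m in models.items():
            save_model(m, outdir / f"model_{key.replace(' ', '_')}.json")
        save_table(train, outdir / "train.csv")
        save_table(test, outdir / "test.csv")
    return PipelineResult(
        reports=reports,
        table=table,
        predictions=predictions,
        models=models,
        grid_tables=grid_tables,
        seeds=seeds,
    )
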