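"""Delimited-text tables and portable JSON model containers.

Feature tables are CSV/TSV with a header row, one row per sample, a
designated label column, and an optional subject column; all remaining
columns must be numeric and finite. Models (linear metric or network
stack) round-trip bit-exactly through JSON: Python's float repr preserves
IEEE doubles, and arrays are stored as nested lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FeatureMatrix
from .exceptions import ParameterError
from .metric import MetricModel
from .pretrain import NetworkStack

__all__ = [
    "load_table",
    "save_table",
    "save_model",
    "load_model",
]


def load_table(
    path: str | Path,
    label_column: str,
    subject_column: str | None = None,
    sep: str | None = None,
) -> FeatureMatrix:
    """Read a delimited feature table; validate numeric, finite features.

    The delimiter is sniffed unless given. Rows with non-finite feature
    values are rejected with an itemized error naming each offending
    (row, column).
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ParameterError(f"missing or empty table: {path}")
    if sep is None:
        header = path.open().readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    # round_trip parsing keeps IEEE doubles bit-exact through save/load
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if label_column not in df.columns:
        raise ParameterError(f"label column {label_column!r} not in {list(df.columns)[:8]}...")
    if subject_column is not None and subject_column not in df.columns:
        raise ParameterError(f"subject column {subject_column!r} not found")
    drop = [label_column] + ([subject_column] if subject_column else [])
    feats = df.drop(columns=drop)
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    mask = ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if mask.any():
        where = np.argwhere(mask)
        items = ", ".join(
            f"(row {r}, column {feats.columns[c]!r})" for r, c in where[:10]
        )
        raise ParameterError(
            f"{mask.sum()} non-finite/non-numeric feature cells: {items}"
            + (", ..." if len(where) > 10 else "")
        )
    return FeatureMatrix(
        numeric.to_numpy(dtype=float),
        df[label_column].to_numpy(),
        list(feats.columns),
        df[subject_column].to_numpy() if subject_column else None,
    )


def save_table(data: FeatureMatrix, path: str | Path, sep: str = ",") -> None:
    """Write a feature table with label (and subject) columns appended."""
    cols = data.feature_names or [f"f{j}" for j in range(data.n_features)]
    df = pd.DataFrame(data.values, columns=cols)
    df["label"] = data.labels
    if data.subjects is not None:
        df["subject"] = data.subjects
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def _arr(x: np.ndarray) -> list:
    return np.asarray(x, dtype=float).tolist()


def save_model(model: MetricModel | NetworkStack, path: str | Path) -> None:
    """Serialize a metric model or network stack to portable JSON."""
    if isinstance(model, MetricModel):
        obj = {
            "kind": "metric",
            "W": _arr(model.W),
            "sigma": model.sigma,
            "d": model.d,
            "mean": _arr(model.mean_),
            "scale": _arr(model.scale_),
            "fit_history": [[int(i), float(c)] for i, c in model.fit_history],
            "seed": model.seed,
            "converged": model.converged,
            "rho_init": model.rho_init,
            "rho_final": model.rho_final,
        }
    elif isinstance(model, NetworkStack):
        obj = {
            "kind": "stack",
            "layers": [[_arr(W), _arr(b)] for W, b in model.layers],
            "sizes": list(model.sizes),
            "activation": model.activation,
            "mean": None if model.mean_ is None else _arr(model.mean_),
            "scale": None if model.scale_ is None else _arr(model.scale_),
            "fit_histories": [
                [[int(i), float(c)] for i, c in h] for h in model.fit_histories
            ],
            "layer_sigmas": list(model.layer_sigmas),
            "layer_alignments": list(model.layer_alignments),
            "seed": model.seed,
        }
    else:
        raise ParameterError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(obj))


def load_model(path: str | Path) -> MetricModel | NetworkStack:
    obj = json.loads(Path(path).read_text())
    if obj["kind"] == "metric":
        return MetricModel(
            W=np.array(obj["W"]),
            sigma=obj["sigma"],
            d=obj["d"],
            mean_=np.array(obj["mean"]),
            scale_=np.array(obj["scale"]),
            fit_history=[(i, c) for i, c in obj["fit_history"]],
            seed=obj["seed"],
            converged=obj["converged"],
            rho_init=obj["rho_init"],
            rho_final=obj["rho_final"],
        )
    if obj["kind"] == "stack":
        return NetworkStack(
            layers=[(np.array(W), np.array(b)) for W, b in obj["layers"]],
            sizes=tuple(obj["sizes"]),
            activation=obj["activation"],
            mean_=None if obj["mean"] is None else np.array(obj["mean"]),
            scale_=None if obj["scale"] is None else np.array(obj["scale"]),
            fit_histories=[[(i, c) for i, c in h] for h in obj["fit_histories"]],
            layer_sigmas=obj["layer_sigmas"],
            layer_alignments=obj["layer_alignments"],
            seed=obj["seed"],
        )
    raise ParameterError(f"unknown model kind {obj.get('kind')!r}")
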