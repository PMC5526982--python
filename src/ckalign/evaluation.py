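"""Performance measures: accuracy, per-class true-positive fractions,
bootstrap confidence intervals, balance dispersion, per-class AUC, and the
baseline-vs-enhanced significance test.

The per-class true-positive fraction tau_c = t_c / N_c is within-class
recall; in a two-class setting the pathological class's tau is the
sensitivity and the control class's tau the specificity. Overall accuracy
equals the class-size-weighted mean of the tau_c, an identity the test
suite asserts. std_tau — the (ddof=1) standard deviation of the tau_c,
reported in percent — summarizes how balanced a classifier is across
classes.

Uncertainty is quantified by a percentile bootstrap over test-set indices
(default 1,000 resamples, 95% interval); a classifier is compared with its
metric-enhanced version by a one-sided Welch t-test at the 1% level on
bootstrap (or per-seed) score vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .exceptions import ParameterError

__all__ = [
    "EvalReport",
    "score",
    "std_tau",
    "bootstrap_ci",
    "compare_significance",
    "per_class_auc",
    "report_table",
    "parse_report_table",
]


@dataclass
class EvalReport:
    """One evaluated configuration: point estimates, CIs, balance, AUCs."""

    name: str
    accuracy: float
    tau: dict
    ci: dict = field(default_factory=dict)  # measure -> (low, high), same scale
    std_tau: float = float("nan")  # percent
    auc: dict = field(default_factory=dict)
    auc_mean: float = float("nan")
    n_resamples: int = 0
    seed: int = 0


def score(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, dict]:
    """Accuracy and per-class true-positive fractions tau_c = t_c / N_c."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ParameterError("label vectors differ in length")
    if y_true.size == 0:
        raise ParameterError("empty label vectors")
    classes = np.unique(y_true)
    tau = {}
    for c in classes:
        mask = y_true == c
        tau[c] = float(np.mean(y_pred[mask] == c))
    accuracy = float(np.mean(y_pred == y_true))
    return accuracy, tau


def std_tau(tau: dict) -> float:
    """Sample standard deviation (ddof=1) of the per-class fractions, in percent."""
    vals = np.array(list(tau.values()), dtype=float)
    if vals.size < 2:
        return 0.0
    return float(np.std(vals, ddof=1) * 100.0)


def _measure_value(measure, y_true, y_pred):
    if measure == "accuracy":
        return float(np.mean(y_pred == y_true))
    if measure == "std_tau":
        _, tau = score(y_true, y_pred)
        return std_tau(tau)
    if isinstance(measure, tuple) and measure[0] == "tau":
        c = measure[1]
        mask = y_true == c
        if not mask.any():
            raise ParameterError("class absent")
        return float(np.mean(y_pred[mask] == c))
    raise ParameterError(f"unknown measure {measure!r}")


def _measure_needs(measure, y_true):
    """Classes a resample must contain for the measure to be defined."""
    if measure == "accuracy":
        return ()
    if measure == "std_tau":
        return tuple(np.unique(y_true))
    if isinstance(measure, tuple) and measure[0] == "tau":
        return (measure[1],)
    raise ParameterError(f"unknown measure {measure!r}")


def bootstrap_ci(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    measure="accuracy",
    B: int = 1000,
    seed: int = 0,
    return_replicates: bool = False,
):
    """Percentile bootstrap over test indices: (mean, low, high) at 95%.

    ``measure`` is "accuracy", "std_tau", or ("tau", class). A resample
    missing a class the measure needs is redrawn (the redraw count is kept
    on the result when replicates are requested). Deterministic for a
    fixed seed.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    n = y_true.size
    needs = _measure_needs(measure, y_true)
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            yt = y_true[idx]
            if all((yt == c).any() for c in needs):
                break
            redraws += 1
        reps[b] = _measure_value(measure, yt, y_pred[idx])
    mean = float(np.mean(reps))
    low, high = (float(q) for q in np.percentile(reps, [2.5, 97.5]))
    if return_replicates:
        return mean, low, high, reps, redraws
    return mean, low, high


def compare_significance(
    baseline: np.ndarray, enhanced: np.ndarray, alpha: float = 0.01
) -> tuple[float, float, bool]:
    """One-sided Welch two-sample t-test for "enhanced exceeds baseline".

    Returns (t statistic, p value, significant at ``alpha``). Two
    zero-variance samples with equal means give p = 1 by convention.
    """
    a = np.asarray(baseline, dtype=float)
    b = np.asarray(enhanced, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("need at least two replicates per sample")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0, False
        t = np.inf if np.mean(b) > np.mean(a) else -np.inf
        return float(t), (0.0 if t > 0 else 1.0), bool(t > 0)
    t, p = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
    return float(t), float(p), bool(p < alpha)


def per_class_auc(y_true: np.ndarray, scores: np.ndarray, classes=None):
    """One-vs-rest rank-based AUC per class (mid-rank ties) and their mean."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ParameterError("scores must be finite")
    if classes is None:
        classes = np.unique(y_true)
    if scores.ndim != 2 or scores.shape != (y_true.size, len(classes)):
        raise ParameterError(
            f"scores shape {scores.shape} != (N={y_true.size}, C={len(classes)})"
        )
    aucs = {}
    for j, c in enumerate(classes):
        pos = y_true == c
        if not pos.any() or pos.all():
            raise ParameterError(f"class {c!r} missing or exhaustive in y_true")
        aucs[c] = float(roc_auc_score(pos.astype(int), scores[:, j]))
    return aucs, float(np.mean(list(aucs.values())))


def _fmt_ci(point: float, lo: float, hi: float) -> str:
    """Percent-scale 'point (low–high)' with one decimal."""
    return f"{100 * point:.1f} ({100 * lo:.1f}–{100 * hi:.1f})"


def report_table(reports: list[EvalReport]) -> pd.DataFrame:
    """Per-configuration summary table, percent scale, 'a (CI)' formatting."""
    rows = []
    for r in reports:
        row = {"configuration": r.name}
        lo, hi = r.ci.get("accuracy", (r.accuracy, r.accuracy))
        row["a (CI)"] = _fmt_ci(r.accuracy, lo, hi)
        for c, t in r.tau.items():
            lo, hi = r.ci.get(("tau", c), (t, t))
            row[f"tau_{c} (CI)"] = _fmt_ci(t, lo, hi)
        row["std_tau (%)"] = f"{r.std_tau:.1f}"
        if r.auc:
            for c, a in r.auc.items():
                row[f"AUC_{c}"] = f"{100 * a:.1f}"
            row["AUC_mean"] = f"{100 * r.auc_mean:.1f}"
        rows.append(row)
    return pd.DataFrame(rows)


def parse_report_table(table: pd.DataFrame) -> list[dict]:
    """Recover numeric values from a formatted report table (round-trip)."""
    out = []
    for _, row in table.iterrows():
        rec: dict = {"configuration": row["configuration"]}
        for col, val in row.items():
            if col == "configuration" or pd.isna(val):
                continue
            s = str(val)
            if "(" in s:
                point, rest = s.split("(")
                lo, hi = rest.rstrip(")").split("–")
                rec[col] = (float(point) / 100, float(lo) / 100, float(hi) / 100)
            else:
                rec[col] = float(s) / (100 if col.startswith("AUC") else 1)
        out.append(rec)
    return out
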