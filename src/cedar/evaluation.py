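"""Benchmark metrics for cell-type-specific differential calling.

Rankings are scored with rank-based AUC-ROC (Mann-Whitney form, midrank
ties), step-interpolated AUC-PR, and the true discovery rate of top-j
lists; binary calls with the Matthews correlation coefficient and the
observed false discovery rate FP / (FP + TP). Replicate summaries report
mean, median, and interquartile range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    matthews_corrcoef,
    roc_auc_score,
    roc_curve,
)

__all__ = [
    "UndefinedMetricError",
    "roc_auc",
    "pr_auc",
    "mcc",
    "observed_fdr",
    "tdr_curve",
    "EvaluationReport",
    "evaluate_cell_type",
    "summarize_replicates",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric needs both classes but only one is present."""


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise UndefinedMetricError("both classes must be present")
    return labels


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; equals the midrank Mann-Whitney statistic."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve by step interpolation."""
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def mcc(calls, labels) -> float:
    """Matthews correlation coefficient of binary calls against truth."""
    calls = np.asarray(calls).astype(int)
    labels = np.asarray(labels).astype(int)
    return float(matthews_corrcoef(labels, calls))


def observed_fdr(calls, labels) -> float | None:
    """FP / (FP + TP) among positive calls; ``None`` with no discoveries."""
    calls = np.asarray(calls).astype(bool)
    labels = np.asarray(labels).astype(bool)
    n_called = int(calls.sum())
    if n_called == 0:
        return None
    fp = int((calls & ~labels).sum())
    return fp / n_called


def tdr_curve(scores, labels, js) -> np.ndarray:
    """True discovery rate of the top-j lists: TDR(j) = #true in top j / j.

    Ties in ``scores`` are broken by original position (stable sort), so
    the curve is deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    order = np.argsort(-scores, kind="stable")
    hits = np.cumsum(labels[order])
    js = np.asarray(js, dtype=int)
    if js.min() < 1 or js.max() > len(scores):
        raise ValueError("list sizes must lie in [1, n]")
    return hits[js - 1] / js


@dataclass
class EvaluationReport:
    """Metrics of one method on one cell type of one replicate."""

    cell_type: str
    auc_roc: float
    auc_pr: float
    mcc: float | None = None
    observed_fdr: float | None = None
    n_called: int | None = None
    tdr: dict[int, float] = field(default_factory=dict)
    roc_points: tuple[np.ndarray, np.ndarray] | None = None


def evaluate_cell_type(
    scores,
    labels,
    cell_type: str = "",
    calls=None,
    tdr_js=(),
    keep_roc: bool = False,
) -> EvaluationReport:
    """Full per-cell-type report from a ranking and optional binary calls."""
    labels_arr = _check_two_classes(labels)
    rep = EvaluationReport(
        cell_type=cell_type,
        auc_roc=roc_auc(scores, labels_arr),
        auc_pr=pr_auc(scores, labels_arr),
    )
    if calls is not None:
        rep.mcc = mcc(calls, labels_arr)
        rep.observed_fdr = observed_fdr(calls, labels_arr)
        rep.n_called = int(np.asarray(calls).astype(bool).sum())
    if len(tdr_js):
        vals = tdr_curve(scores, labels_arr, tdr_js)
        rep.tdr = dict(zip((int(j) for j in tdr_js), vals))
    if keep_roc:
        fpr, tpr, _ = roc_curve(labels_arr, np.asarray(scores, dtype=float))
        rep.roc_points = (fpr, tpr)
    return rep


def summarize_replicates(values: pd.DataFrame) -> pd.DataFrame:
    """Mean / median / IQR per column over replicate rows (NaNs dropped)."""
    out = pd.DataFrame(
        {
            "mean": values.mean(),
            "median": values.median(),
            "q25": values.quantile(0.25),
            "q75": values.quantile(0.75),
        }
    )
    out["iqr"] = out["q75"] - out["q25"]
    return out
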