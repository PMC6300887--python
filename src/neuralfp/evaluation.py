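"""Three-view multi-label evaluation: global, per-ADR (column), per-drug (row).

Given an N x M binary label matrix and an N x M score matrix, the global
view flattens both; the column view averages per-ADR metrics (macro); the
row view averages per-drug retrieval metrics including precision at K.
Threshold-based metrics use a fixed cutoff (default 0.5); AUC and AUPR use
the raw scores.  Columns where AUC is undefined (a single class) are
excluded from the AUC average and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class EvalReport:
    view: str  # "global" | "column" | "row"
    metrics: dict[str, float]
    per_unit: list[dict] = field(default_factory=list)
    notes: dict[str, int] = field(default_factory=dict)


def _confusion_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    """Accuracy/precision/recall/specificity/F1 with 0-for-undefined convention."""
    tp = float(np.sum((yhat == 1) & (y == 1)))
    tn = float(np.sum((yhat == 0) & (y == 0)))
    fp = float(np.sum((yhat == 1) & (y == 0)))
    fn = float(np.sum((yhat == 0) & (y == 1)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    specificity = tn / (tn + fp) if tn + fp > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return {
        "accuracy": (tp + tn) / len(y),
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
    }


def _check(y: np.ndarray, s: np.ndarray):
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    if y.shape != s.shape:
        raise ValueError(f"label shape {y.shape} != score shape {s.shape}")
    return y, s


def global_metrics(y: np.ndarray, s: np.ndarray, threshold: float = 0.5) -> EvalReport:
    """All N*M cells compared at once."""
    y, s = _check(y, s)
    yf, sf = y.ravel(), s.ravel()
    metrics = _confusion_metrics(yf, (sf >= threshold).astype(int))
    notes = {}
    if len(np.unique(yf)) == 2:
        metrics["auc"] = float(roc_auc_score(yf, sf))
        metrics["aupr"] = float(average_precision_score(yf, sf))
    else:
        notes["auc_undefined"] = 1
    return EvalReport(view="global", metrics=metrics, notes=notes)


def columnwise_metrics(y: np.ndarray, s: np.ndarray, threshold: float = 0.5) -> EvalReport:
    """Per-ADR metrics, macro-averaged across columns."""
    y, s = _check(y, s)
    if y.ndim != 2:
        raise ValueError("columnwise evaluation needs 2-D matrices")
    per_unit = []
    skipped_auc = 0
    for j in range(y.shape[1]):
        col = _confusion_metrics(y[:, j], (s[:, j] >= threshold).astype(int))
        if len(np.unique(y[:, j])) == 2:
            col["auc"] = float(roc_auc_score(y[:, j], s[:, j]))
            col["aupr"] = float(average_precision_score(y[:, j], s[:, j]))
        else:
            skipped_auc += 1
        col["column"] = j
        per_unit.append(col)
    names = ["accuracy", "precision", "recall", "specificity", "f1", "auc", "aupr"]
    metrics = {}
    for name in names:
        vals = [u[name] for u in per_unit if name in u]
        if vals:
            metrics[name] = float(np.mean(vals))
    return EvalReport(view="column", metrics=metrics, per_unit=per_unit,
                      notes={"columns_without_auc": skipped_auc})


def precision_at_k(y_row: np.ndarray, s_row: np.ndarray, k: int = 10) -> float:
    """Fraction of the k highest-scored ADRs that are true positives.

    Ties are broken by ADR index (stable sort); rows with fewer than k ADRs
    use all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    y_row = np.asarray(y_row).ravel()
    s_row = np.asarray(s_row, dtype=float).ravel()
    order = np.argsort(-s_row, kind="stable")
    top = order[: min(k, len(s_row))]
    return float(np.mean(y_row[top]))


def rowwise_metrics(y: np.ndarray, s: np.ndarray, threshold: float = 0.5, k: int = 10) -> EvalReport:
    """Per-drug retrieval metrics incl. P@k, macro-averaged across rows."""
    y, s = _check(y, s)
    if y.ndim != 2:
        raise ValueError("rowwise evaluation needs 2-D matrices")
    per_unit = []
    for i in range(y.shape[0]):
        row = _confusion_metrics(y[i], (s[i] >= threshold).astype(int))
        del row["specificity"]  # row view reports retrieval metrics only
        row[f"p_at_{k}"] = precision_at_k(y[i], s[i], k)
        row["row"] = i
        per_unit.append(row)
    names = ["accuracy", "precision", "recall", "f1", f"p_at_{k}"]
    metrics = {name: float(np.mean([u[name] for u in per_unit])) for name in names}
    return EvalReport(view="row", metrics=metrics, per_unit=per_unit)


def evaluate_all(y: np.ndarray, s: np.ndarray, threshold: float = 0.5, k: int = 10) -> dict[str, EvalReport]:
    return {
        "global": global_metrics(y, s, threshold),
        "column": columnwise_metrics(y, s, threshold),
        "row": rowwise_metrics(y, s, threshold, k),
    }
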