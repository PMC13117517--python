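"""Multiclass evaluation metrics with bootstrap confidence intervals.

Balanced accuracy and Cohen's kappa are computed from the confusion matrix
directly; one-vs-rest AUC-ROC and AUC-PR delegate to scikit-learn's
rank-based implementations (midrank tie handling, step-interpolated
average precision) behind this module's macro/micro averaging rules:
macro averages skip classes with no positives or no negatives in the
ground truth (with a warning) rather than scoring them zero; micro
averaging flattens the (indicator, probability) pairs across all classes.

Confidence intervals are percentile bootstrap with the slide as the
resampling unit, 1000 repetitions at the 95% level by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "MetricReport",
    "balanced_accuracy",
    "cohens_kappa",
    "auc_roc",
    "auc_pr",
    "bootstrap_ci",
    "metric_suite",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    """Point estimate plus a percentile-bootstrap confidence interval."""

    metric_name: str
    point: float
    ci_low: float
    ci_high: float
    n_boot: int = 1000
    level: float = 0.95
    seed: int = 0


def _check_labels(y_true, y_pred_or_probs) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true)
    other = np.asarray(y_pred_or_probs)
    if y_true.size == 0:
        raise ValueError("empty input")
    if len(y_true) != len(other):
        raise ValueError("length mismatch")
    return y_true, other


def balanced_accuracy(y_true, y_pred) -> float:
    """Unweighted mean of per-class recall over classes present in y_true."""
    y_true, y_pred = _check_labels(y_true, y_pred)
    recalls = []
    for c in np.unique(y_true):
        mask = y_true == c
        recalls.append(np.mean(y_pred[mask] == c))
    return float(np.mean(recalls))


def cohens_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement, kappa = (p_o - p_e) / (1 - p_e)."""
    y_true, y_pred = _check_labels(y_true, y_pred)
    n = len(y_true)
    classes = np.union1d(np.unique(y_true), np.unique(y_pred))
    p_o = np.mean(y_true == y_pred)
    p_e = sum(np.mean(y_true == c) * np.mean(y_pred == c) for c in classes)
    if p_e >= 1.0 - 1e-15:
        # both raters constant and identical: perfect, degenerate agreement
        logger.warning("kappa degenerate (p_e = 1); returning 1.0 by convention")
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def _one_hot(y: np.ndarray, c: int) -> np.ndarray:
    out = np.zeros((len(y), c))
    out[np.arange(len(y)), y] = 1.0
    return out


def _ovr_average(y_true, probs, average: str, scorer: Callable) -> float:
    y_true, probs = _check_labels(y_true, probs)
    if probs.ndim != 2:
        raise ValueError("probs must be an (n, C) matrix")
    c = probs.shape[1]
    onehot = _one_hot(y_true, c)
    if average == "micro":
        return float(scorer(onehot.ravel(), probs.ravel()))
    if average != "macro":
        raise ValueError(f"unknown average {average!r}")
    per_class = []
    for j in range(c):
        pos = onehot[:, j].sum()
        if pos == 0 or pos == len(y_true):
            logger.warning("class %d has no positives or no negatives; "
                           "excluded from macro average", j)
            continue
        per_class.append(scorer(onehot[:, j], probs[:, j]))
    if not per_class:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(per_class))


def auc_roc(y_true, probs, average: str = "macro") -> float:
    """One-vs-rest area under the ROC curve, macro or micro averaged."""
    return _ovr_average(y_true, probs, average, roc_auc_score)


def auc_pr(y_true, probs, average: str = "macro") -> float:
    """One-vs-rest average precision (area under the PR curve)."""
    return _ovr_average(y_true, probs, average, average_precision_score)


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    y_true,
    y_score_or_pred,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    metric_name: str = "metric",
) -> MetricReport:
    """Percentile bootstrap CI; the resampling unit is the slide.

    Resamples on which the metric is undefined (for instance a class
    vanishing from an AUC resample) are redrawn; the redraw count is
    logged.
    """
    y_true, other = _check_labels(y_true, y_score_or_pred)
    n = len(y_true)
    if n < 2:
        raise ValueError("need at least 2 observations to bootstrap")
    point = float(metric_fn(y_true, other))
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                stats[b] = metric_fn(y_true[idx], other[idx])
                break
            except ValueError:
                redraws += 1
                if redraws > 100 * n_boot:
                    raise RuntimeError("metric undefined on almost every resample")
    if redraws:
        logger.info("bootstrap redrew %d degenerate resample(s)", redraws)
    lo, hi = np.percentile(stats, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return MetricReport(metric_name=metric_name, point=point,
                        ci_low=float(lo), ci_high=float(hi),
                        n_boot=n_boot, level=level, seed=seed)


def metric_suite(y_true, y_pred, probs) -> dict[str, float]:
    """The six study metrics; AUCs are NaN when undefined on tiny sets."""
    out = {
        "balanced_accuracy": balanced_accuracy(y_true, y_pred),
        "cohens_kappa": cohens_kappa(y_true, y_pred),
    }
    for name, avg, fn in [
        ("auc_roc_macro", "macro", auc_roc), ("auc_roc_micro", "micro", auc_roc),
        ("auc_pr_macro", "macro", auc_pr), ("auc_pr_micro", "micro", auc_pr),
    ]:
        try:
            out[name] = fn(y_true, probs, avg)
        except ValueError:
            out[name] = float("nan")
    return out
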