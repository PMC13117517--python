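"""Non-parametric model comparison: Wilcoxon, Friedman, Nemenyi, CD diagram.

The comparison unit is the per-run test metric: with 10 repeated random
splits shared across architectures, each model contributes one paired value
per run. Pairwise comparisons use the Wilcoxon signed-rank test (exact by
dynamic programming up to n = 25 paired differences, normal approximation
with tie correction beyond); the omnibus test is the tie-corrected Friedman
statistic; post-hoc pairwise significance uses the Nemenyi critical
difference CD = q_alpha(m) * sqrt(m (m + 1) / (6 n)), with the
Studentized-range-derived q table (two-tailed, infinite df, divided by
sqrt(2)) embedded for m <= 20.

Ranks run 1 = best, i.e. the highest metric value, as in a standard
critical-difference diagram where lower rank is better.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "RankMatrix",
    "wilcoxon_signed_rank",
    "friedman_test",
    "nemenyi_cd",
    "cd_diagram_data",
    "rank_models",
    "pairwise_wilcoxon_table",
]

logger = logging.getLogger(__name__)

# Critical values q_alpha(m) for the Nemenyi test: two-tailed Studentized
# range at infinite df divided by sqrt(2); index = number of models m.
_Q_NEMENYI = {
    0.05: [None, None, 1.959964, 2.343701, 2.569032, 2.727774, 2.849705,
           2.948319, 3.030879, 3.101730, 3.163684, 3.218654, 3.268004,
           3.312739, 3.353618, 3.391230, 3.426041, 3.458425, 3.488685,
           3.517073, 3.543799],
    0.10: [None, None, 1.644854, 2.052293, 2.291341, 2.459516, 2.588521,
           2.692732, 2.779884, 2.854606, 2.919889, 2.977768, 3.029694,
           3.076733, 3.119693, 3.159199, 3.195743, 3.229723, 3.261461,
           3.291224, 3.319233],
    0.01: [None, None, 2.575829, 2.913494, 3.113250, 3.254685, 3.363740,
           3.452212, 3.526470, 3.590339, 3.646291, 3.696020, 3.740733,
           3.781318, 3.818450, 3.852654, 3.884343, 3.913850, 3.941446,
           3.967356, 3.991769],
}


@dataclass
class RankMatrix:
    """Per-run performance values with their within-run ranks (1 = best)."""

    values: np.ndarray       # (n_runs, m_models)
    ranks: np.ndarray        # same shape, midranks for ties
    avg_ranks: np.ndarray    # (m_models,)
    model_names: list[str]


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original treatment); ties in
    |d| get midranks. The statistic is W = min(W+, W-). The p-value is
    exact — computed by convolution over the 2^n equiprobable sign
    assignments, conditional on the observed ranks — for n <= 25 retained
    pairs, and a tie-corrected normal approximation beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d paired samples")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        logger.warning("all paired differences are zero; p = 1")
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    stat = min(w_pos, w_neg)
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w_pos)
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts ** 3 - counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_pos - mean) / np.sqrt(var)
        p = 2.0 * norm.sf(abs(z))
    return stat, float(min(p, 1.0))


def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """P-value over all 2^n sign assignments by integer convolution.

    Midranks are multiples of 1/2, so doubling makes every rank integral
    and the distribution of 2*W+ exact.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = r2.sum()
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:-r].copy() if r > 0 else counts
    n = len(ranks)
    denom = 2.0 ** n
    w2 = int(round(2 * w_pos))
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def rank_models(values: np.ndarray, model_names: list[str] | None = None) -> RankMatrix:
    """Within-run ranks, 1 for the highest value, midranks for ties."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a runs x models matrix")
    ranks = np.vstack([rankdata(-row) for row in values])
    names = model_names or [f"model{j}" for j in range(values.shape[1])]
    return RankMatrix(values=values, ranks=ranks,
                      avg_ranks=ranks.mean(axis=0), model_names=names)


def friedman_test(values: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square over a runs x models matrix.

    chi2_F = (m-1) [sum_j R_j^2 - n^2 m (m+1)^2 / 4]
             / [sum_ij r_ij^2 - n m (m+1)^2 / 4],
    which reduces to the classic 12n/(m(m+1)) sum (Rbar_j - (m+1)/2)^2
    in the absence of ties. p from chi-square with m - 1 df.
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if m < 3:
        raise ValueError("Friedman needs at least 3 models; use the Wilcoxon "
                         "signed-rank test for two")
    if n < 2:
        raise ValueError("need at least 2 runs")
    ranks = np.vstack([rankdata(row) for row in values])
    col_sums = ranks.sum(axis=0)
    correction = n * m * (m + 1) ** 2 / 4.0
    denom = (ranks ** 2).sum() - correction
    if denom <= 0:
        return 0.0, 1.0
    stat = (m - 1) * ((col_sums ** 2).sum() - n * correction) / denom
    return float(stat), float(chi2.sf(stat, m - 1))


def nemenyi_cd(m_models: int, n_runs: int, alpha: float = 0.05) -> float:
    """Critical difference of average ranks for the Nemenyi post-hoc test."""
    if m_models < 2 or n_runs < 1:
        raise ValueError("need m >= 2 models and n >= 1 runs")
    if alpha not in _Q_NEMENYI:
        raise ValueError(f"alpha must be one of {sorted(_Q_NEMENYI)}")
    table = _Q_NEMENYI[alpha]
    if m_models >= len(table):
        raise ValueError(f"embedded q table covers m <= {len(table) - 1} models")
    q = table[m_models]
    return float(q * np.sqrt(m_models * (m_models + 1) / (6.0 * n_runs)))


def cd_diagram_data(
    values: np.ndarray,
    model_names: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[np.ndarray, float, list[list[str]]]:
    """Average ranks, critical difference, and the CD-diagram cliques.

    Cliques are the maximal groups of models whose pairwise average-rank
    gaps are all below the CD — the connector bars of a critical-difference
    diagram. Because "within CD of each other" on a line is an interval
    relation, maximal cliques are maximal windows of the rank-sorted models.
    """
    rm = rank_models(values, model_names)
    cd = nemenyi_cd(values.shape[1], values.shape[0], alpha)
    order = np.argsort(rm.avg_ranks, kind="stable")
    sorted_ranks = rm.avg_ranks[order]
    m = len(order)
    windows = []
    for i in range(m):
        j = i
        while j + 1 < m and sorted_ranks[j + 1] - sorted_ranks[i] < cd:
            j += 1
        windows.append((i, j))
    maximal = [(i, j) for (i, j) in windows
               if not any(a <= i and j <= b and (a, b) != (i, j) for a, b in windows)]
    cliques = [[rm.model_names[order[k]] for k in range(i, j + 1)] for i, j in maximal]
    return rm.avg_ranks, cd, cliques


def pairwise_wilcoxon_table(
    results: pd.DataFrame,
    metric: str = "balanced_accuracy",
) -> pd.DataFrame:
    """All pairwise Wilcoxon tests from a tidy (run_id, model, metric, value) table."""
    sub = results[results["metric"] == metric]
    wide = sub.pivot(index="run_id", columns="model", values="value")
    rows = []
    for a, b in itertools.combinations(wide.columns, 2):
        stat, p = wilcoxon_signed_rank(wide[a].to_numpy(), wide[b].to_numpy())
        rows.append({"model_a": a, "model_b": b, "statistic": stat, "p_value": p})
    return pd.DataFrame(rows)
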