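"""Classification metrics and the statistical method-comparison layer.

Metrics: accuracy, per-class one-vs-rest precision/recall/F1 from
confusion counts, and the macro ("average") F1 score AF1 — the unweighted
mean of per-class F1, robust under class imbalance.

Comparison: the Friedman rank test across methods measured on the same
runs, the Nemenyi post-hoc on average-rank differences via the
studentized-range distribution, a Bonferroni-adjusted significance
threshold for the resulting pairwise grid, and rank-table aggregation
(per-dataset ranks and their column means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MetricReport",
    "RankMatrix",
    "classification_metrics",
    "friedman_test",
    "nemenyi_posthoc",
    "bonferroni_threshold",
    "rank_table",
    "aggregate_ranks",
]


@dataclass(frozen=True)
class MetricReport:
    """Accuracy, per-class confusion counts, precision/recall/F1, and AF1."""

    accuracy: float
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    af1: float

    @property
    def n_classes(self) -> int:
        return len(self.f1)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "af1": self.af1,
            "per_class_f1": self.f1.tolist(),
            "per_class_precision": self.precision.tolist(),
            "per_class_recall": self.recall.tolist(),
        }


def classification_metrics(y_true, y_pred, c: int | None = None) -> MetricReport:
    """Accuracy, one-vs-rest precision/recall/F1 per class, and macro AF1.

    Zero-denominator precision or recall is set to 0 (standard macro-F1
    convention), so a class never predicted and never present contributes
    an F1 of 0 rather than an undefined value.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if c is None:
        c = int(max(y_true.max(), y_pred.max())) + 1
    if y_true.min() < 0 or y_true.max() >= c or y_pred.min() < 0 or y_pred.max() >= c:
        raise ValueError(f"labels must lie in 0..{c - 1}")

    n = len(y_true)
    tp = np.zeros(c)
    fp = np.zeros(c)
    fn = np.zeros(c)
    for k in range(c):
        tp[k] = np.sum((y_true == k) & (y_pred == k))
        fp[k] = np.sum((y_true != k) & (y_pred == k))
        fn[k] = np.sum((y_true == k) & (y_pred != k))
    tn = n - tp - fp - fn

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1.0), 0.0)

    return MetricReport(
        accuracy=float(np.mean(y_true == y_pred)),
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        af1=float(f1.mean()),
    )


def _rank_rows(perf: np.ndarray) -> np.ndarray:
    """Within-run ranks (1 = smallest value), average ranks on ties."""
    return np.apply_along_axis(sps.rankdata, 1, perf)


def friedman_test(perf: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square test across methods (columns) over runs (rows).

    Uses average ranks on ties and the tie-corrected statistic; the
    p-value comes from the chi-square approximation with k-1 degrees of
    freedom.  An input whose rows are all constant carries no ranking
    information and returns statistic 0 with p = 1 (by convention, not an
    error).
    """
    perf = np.asarray(perf, dtype=float)
    if perf.ndim != 2 or perf.shape[0] < 2 or perf.shape[1] < 2:
        raise ValueError(f"need a (runs >= 2) x (methods >= 2) matrix; got {perf.shape}")
    n, k = perf.shape
    ranks = _rank_rows(perf)
    column_sums = ranks.sum(axis=0)
    statistic = (12.0 / (n * k * (k + 1))) * np.sum(column_sums**2) - 3.0 * n * (k + 1)

    # tie correction: deflate by 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in perf:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k * k - 1))
    if correction <= 0.0 or statistic <= 0.0:
        return 0.0, 1.0
    statistic /= correction
    return float(statistic), float(sps.chi2.sf(statistic, k - 1))


def nemenyi_posthoc(perf: np.ndarray) -> np.ndarray:
    """Pairwise Nemenyi p-values on average-rank differences.

    The standardised rank difference ``|R_i - R_j| / sqrt(k(k+1)/(6n))``
    is referred (after the sqrt(2) convention) to the studentized-range
    distribution with k groups and infinite degrees of freedom.  The
    returned k x k matrix is symmetric with unit diagonal; identical
    columns give all off-diagonal p-values of 1.
    """
    perf = np.asarray(perf, dtype=float)
    if perf.ndim != 2 or perf.shape[0] < 2 or perf.shape[1] < 2:
        raise ValueError(f"need a (runs >= 2) x (methods >= 2) matrix; got {perf.shape}")
    n, k = perf.shape
    avg_ranks = _rank_rows(perf).mean(axis=0)
    scale = np.sqrt(k * (k + 1) / (6.0 * n))
    q = np.abs(avg_ranks[:, None] - avg_ranks[None, :]) / scale * np.sqrt(2.0)
    p = sps.studentized_range.sf(q, k, np.inf)
    p = np.clip(p, 0.0, 1.0)
    np.fill_diagonal(p, 1.0)
    return p


def bonferroni_threshold(k_methods: int, alpha: float = 0.05) -> tuple[int, float]:
    """Number of pairwise comparisons c = k(k-1)/2 and alpha / c."""
    if k_methods < 2:
        raise ValueError(f"need at least 2 methods; got {k_methods}")
    comparisons = k_methods * (k_methods - 1) // 2
    return comparisons, alpha / comparisons


@dataclass(frozen=True)
class RankMatrix:
    """Per-dataset method ranks (1 = best) with column average ranks."""

    ranks: pd.DataFrame
    average: pd.Series

    @classmethod
    def from_scores(cls, scores: pd.DataFrame, higher_is_better: bool = True) -> "RankMatrix":
        if scores.isna().any().any():
            raise ValueError("score table contains NaN cells")
        ranks = scores.rank(axis=1, ascending=not higher_is_better, method="average")
        return cls(ranks=ranks, average=ranks.mean(axis=0))

    @classmethod
    def from_ranks(cls, ranks: pd.DataFrame) -> "RankMatrix":
        if ranks.isna().any().any():
            raise ValueError("rank table contains NaN cells")
        return cls(ranks=ranks.astype(float), average=ranks.astype(float).mean(axis=0))


def rank_table(best_af1: pd.DataFrame) -> RankMatrix:
    """Rank methods within each dataset row by descending AF1.

    Average ranks are assigned on ties; the column means give each
    method's overall average rank across datasets.
    """
    return RankMatrix.from_scores(best_af1, higher_is_better=True)


def aggregate_ranks(rank_rows: pd.DataFrame) -> pd.Series:
    """Column-mean aggregation of an already-ranked datasets x methods table."""
    return RankMatrix.from_ranks(rank_rows).average
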