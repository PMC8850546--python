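"""Kruskal–Wallis feature ranking and top-N selection.

Each feature column is scored by the two-group Kruskal–Wallis H statistic
(rank-based, with mid-rank tie correction); the p-value comes from the
chi-square approximation with one degree of freedom. Features are ranked by
H descending (ties broken by lower column index) and the top N retained in
their original column order. With two groups this is equivalent to the
Wilcoxon rank-sum test up to the chi-square approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, rankdata

from .encoders import FeatureMatrix


@dataclass
class FeatureRanking:
    """Per-feature H and p, plus the rank order (best first)."""

    names: list
    h: np.ndarray
    p: np.ndarray
    order: np.ndarray  # column indices sorted by H desc, ties by index asc

    def __post_init__(self):
        if not (len(self.names) == len(self.h) == len(self.p) == len(self.order)):
            raise ValueError("ranking arrays must have equal length")

    def top(self, n: int) -> np.ndarray:
        """Column indices of the n best features, in original column order."""
        return np.sort(self.order[:n])

    def to_rows(self):
        """(name, H, p, rank) rows in rank order, for TSV output."""
        return [(self.names[j], float(self.h[j]), float(self.p[j]), r + 1)
                for r, j in enumerate(self.order)]


def kw_statistic(values, labels) -> tuple[float, float]:
    """Two-group Kruskal–Wallis H and chi-square p-value (1 df).

    H = 12/(N(N+1)) * sum_i n_i * Rbar_i^2 - 3(N+1), corrected for ties by
    dividing by 1 - sum(t^3 - t)/(N^3 - N). A feature constant across all
    windows has no rank separation: returns (0, 1).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    x1 = values[labels == 1]
    x2 = values[labels != 1]
    if len(x1) == 0 or len(x2) == 0:
        raise ValueError("both groups must be non-empty")
    n = len(values)
    ranks = rankdata(values)
    r1 = ranks[labels == 1].mean()
    r2 = ranks[labels != 1].mean()
    h = (12.0 / (n * (n + 1))) * (len(x1) * r1 ** 2 + len(x2) * r2 ** 2) - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    correction = 1.0 - tie_term / (n ** 3 - n)
    if correction == 0.0:  # all values identical
        return 0.0, 1.0
    h = max(h / correction, 0.0)
    return float(h), float(chi2.sf(h, df=1))


def rank_features(fm: FeatureMatrix, labels=None) -> FeatureRanking:
    """Rank every column of *fm* by the Kruskal–Wallis H statistic."""
    y = fm.labels if labels is None else np.asarray(labels)
    if (y == 1).sum() == 0 or (y != 1).sum() == 0:
        raise ValueError("both groups must be non-empty")
    d = fm.X.shape[1]
    h = np.empty(d)
    p = np.empty(d)
    for j in range(d):
        h[j], p[j] = kw_statistic(fm.X[:, j], y)
    order = np.lexsort((np.arange(d), -h))
    return FeatureRanking(list(fm.names), h, p, order)


def select_top_n(fm: FeatureMatrix, labels, n: int) -> tuple[FeatureMatrix, FeatureRanking]:
    """Retain the n top-ranked columns (original column order) plus the ranking."""
    d = fm.X.shape[1]
    if not 1 <= n <= d:
        raise ValueError(f"n must be in [1, {d}], got {n}")
    ranking = rank_features(fm, labels)
    keep = ranking.top(n)
    return fm.select_columns(keep), ranking


def write_ranking_tsv(ranking: FeatureRanking, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("name\tH\tp\trank\n")
        for name, h, p, rank in ranking.to_rows():
            fh.write(f"{name}\t{h:.10g}\t{p:.10g}\t{rank}\n")
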