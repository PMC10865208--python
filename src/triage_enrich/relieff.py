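"""Multiclass ReliefF feature ranking and threshold selection.

ReliefF scores each feature by contrasting its value differences between
neighbouring same-class instances ("near hits", NH) and neighbouring
instances of every other class ("near misses", NM): a feature that
separates classes shows small differences to hits and large differences
to misses. For every sampled instance the k nearest hits and the k
nearest misses *per other class* are found (distance = sum of
range-normalized per-feature differences), and each feature's weight W
accumulates

    W[f] += ( sum_{c != class(x)} w_c * meandiff_f(x, NM_c)
              - meandiff_f(x, NH) ) / m

where w_c weights the miss classes (uniform, or by class prior
P(c)/(1 - P(class(x)))). Larger W means more class-relevant. A
complementary raw score S with the opposite orientation
(mean hit-diff minus mean miss-diff, unweighted) is reported alongside.

Per-feature differences are |x_i - x_j| / range(f); a difference
involving a missing value contributes the feature's mean observed
normalized difference, which keeps incomplete rows usable. Constant
features have zero difference everywhere and weight exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import FeatureTable

__all__ = ["ReliefFConfig", "FeatureRanking", "relieff_rank", "select_features"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReliefFConfig:
    """Knobs of the ReliefF ranking.

    m: number of sampled instances; None means every training row
       (deterministic). k: neighbours per class. tau: selection threshold
       on the final weight W.
    """

    m: int | None = None
    k: int = 50
    tau: float = 0.07
    miss_weighting: str = "class_prior"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.miss_weighting not in ("uniform", "class_prior"):
            raise ValueError(f"unknown miss_weighting {self.miss_weighting!r}")


@dataclass
class FeatureRanking:
    """Complete ranking of the features by decreasing weight W."""

    feature_names: list[str]
    weights: np.ndarray          # W, larger = more relevant
    scores: np.ndarray           # S, raw hit-minus-miss orientation
    tau: float

    @property
    def order(self) -> np.ndarray:
        """Indices of features by decreasing W (stable on ties)."""
        return np.argsort(-self.weights, kind="stable")

    @property
    def ranks(self) -> np.ndarray:
        """rank[i] = 1-based rank of feature i."""
        r = np.empty(len(self.weights), dtype=int)
        r[self.order] = np.arange(1, len(self.weights) + 1)
        return r

    @property
    def selected(self) -> list[str]:
        """Feature names with W >= tau, in rank order (a prefix of the ranking)."""
        return [self.feature_names[i] for i in self.order if self.weights[i] >= self.tau]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "W": self.weights,
                "S": self.scores,
                "rank": self.ranks,
                "selected": [w >= self.tau for w in self.weights],
            }
        ).sort_values("rank").reset_index(drop=True)


def _mean_observed_normdiff(col: np.ndarray, rng_width: float) -> float:
    """Mean over observed pairs of |x_i - x_j| / range, via the sorted-values identity."""
    v = np.sort(col[~np.isnan(col)])
    n = len(v)
    if n < 2 or rng_width <= 0:
        return 0.0
    i = np.arange(n)
    total = float(((2 * i - (n - 1)) * v).sum())  # = sum_{i<j} (v_j - v_i)
    return total / (n * (n - 1) / 2) / rng_width


def relieff_rank(train: FeatureTable, cfg: ReliefFConfig) -> FeatureRanking:
    """Rank the features of a training table by ReliefF weight.

    Deterministic when m covers all rows (the default); otherwise the
    sampled instances are drawn with the config seed. Classes with fewer
    than k+1 members get k clamped per class (warning logged once).
    """
    X = train.features.to_numpy(dtype=float)
    y = train.labels
    n, M = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ReliefF needs at least 2 classes")
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    count_of = dict(zip(classes.tolist(), counts.tolist()))
    if any(cnt <= cfg.k for cnt in counts):
        log.warning(
            "some class has <= k=%d members; neighbour count clamped per class", cfg.k
        )

    # per-feature range and mean observed diff (for missing-value handling)
    with np.errstate(all="ignore"):
        lo = np.nanmin(X, axis=0)
        hi = np.nanmax(X, axis=0)
    width = np.where(np.isfinite(hi - lo), hi - lo, 0.0)
    mean_diff = np.array(
        [_mean_observed_normdiff(X[:, f], width[f]) for f in range(M)]
    )

    nanmask = np.isnan(X)

    # distance matrix: sum over features of normalized diffs, missing -> mean diff
    D = np.zeros((n, n))
    for f in range(M):
        if width[f] <= 0:
            continue
        col = X[:, f]
        diff = np.abs(col[:, None] - col[None, :]) / width[f]
        col_nan = np.isnan(col)
        if col_nan.any():
            diff[col_nan, :] = mean_diff[f]
            diff[:, col_nan] = mean_diff[f]
        D += diff
    np.fill_diagonal(D, np.inf)

    if cfg.m is None or cfg.m >= n:
        sampled = np.arange(n)
    else:
        sampled = np.random.default_rng(cfg.seed).choice(n, size=cfg.m, replace=False)
    m_eff = len(sampled)

    idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
    W = np.zeros(M)
    S = np.zeros(M)
    for i in sampled:
        ci = y[i]
        # per-feature normalized diffs from instance i to every row
        diffs_i = _instance_diffs(X, i, width, mean_diff, nanmask)
        hit_pool = idx_by_class[ci]
        k_hit = min(cfg.k, count_of[ci] - 1)
        if k_hit < 1:
            raise ValueError(f"class {ci} has a single member; cannot form near hits")
        hits = hit_pool[np.argsort(D[i, hit_pool], kind="stable")[:k_hit]]
        hit_avg = diffs_i[hits].mean(axis=0)

        miss_term = np.zeros(M)
        all_miss_avgs = []
        for c in classes:
            if c == ci:
                continue
            pool = idx_by_class[c]
            k_miss = min(cfg.k, count_of[c])
            near = pool[np.argsort(D[i, pool], kind="stable")[:k_miss]]
            miss_avg = diffs_i[near].mean(axis=0)
            all_miss_avgs.append(miss_avg)
            if cfg.miss_weighting == "class_prior":
                w_c = priors[c] / (1.0 - priors[ci])
            else:
                w_c = 1.0 / (len(classes) - 1)
            miss_term += w_c * miss_avg
        W += (miss_term - hit_avg) / m_eff
        S += (hit_avg - np.mean(all_miss_avgs, axis=0)) / m_eff

    return FeatureRanking(
        feature_names=train.feature_names, weights=W, scores=S, tau=cfg.tau
    )


def _instance_diffs(
    X: np.ndarray,
    i: int,
    width: np.ndarray,
    mean_diff: np.ndarray,
    nanmask: np.ndarray,
) -> np.ndarray:
    """(n, M) normalized per-feature diffs between row i and every row."""
    width_safe = np.where(width > 0, width, 1.0)
    d = np.abs(X - X[i]) / width_safe
    # any diff touching a missing value contributes the feature's mean diff
    if nanmask.any():
        fill = np.broadcast_to(mean_diff, X.shape)
        d = np.where(nanmask | nanmask[i], fill, d)
    d[:, width <= 0] = 0.0
    return d


def select_features(ranking: FeatureRanking, table: FeatureTable) -> FeatureTable:
    """Restrict a table to the thresholded features, ordered by rank.

    Raises when no feature clears tau — lower tau (or inspect the
    ranking) rather than proceeding with an empty feature set.
    """
    selected = ranking.selected
    if not selected:
        raise ValueError(
            f"no feature has W >= tau={ranking.tau}; max W is "
            f"{float(np.max(ranking.weights)):.4f} — lower tau"
        )
    return table.restrict_features(selected)
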