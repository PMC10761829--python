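"""Feature ranking: greedy MRMR and univariate chi-square.

MRMR (minimum redundancy, maximum relevance) greedily selects the
feature maximising ``MI(f; y) - mean MI(f; selected)`` — the MID
(mutual-information difference) scheme, with features discretised into
equal-frequency bins and base-2 mutual information.  The chi-square
ranker scores each feature by the Pearson statistic of its bin-by-class
contingency table.  Both are deterministic; ties break by feature order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import mutual_info_score
from sklearn.utils.validation import check_is_fitted, validate_data


@dataclass
class RankingResult:
    """Features in ranked order with the score assigned at ranking time."""

    features: list[str]
    scores: list[float]
    method: str


def _discretize_freq(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning (quantile edges; degenerate edges merge)."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def _discretize_width(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width binning over the observed range."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros(len(x), dtype=int)
    return np.minimum(((x - lo) / (hi - lo) * bins).astype(int), bins - 1)


class MRMRRanker(SelectorMixin, BaseEstimator):
    """Greedy MRMR-MID feature ranking as a sklearn selector.

    Parameters
    ----------
    n_bins : int
        Equal-frequency bins used to discretise each feature before
        mutual-information estimation.
    k : int or None
        Features kept by ``transform`` (None keeps all, i.e. the
        transformer only reorders conceptually and selects nothing out).

    Attributes
    ----------
    ranking_ : ndarray of int
        Feature indices in selection order.
    scores_ : ndarray of float
        Greedy objective (relevance minus mean redundancy) at the moment
        each feature was selected; the first entry is pure relevance.
    """

    def __init__(self, n_bins: int = 16, k: int | None = None):
        self.n_bins = n_bins
        self.k = k

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("MRMR needs at least 2 classes")
        n_feat = X.shape[1]
        if n_feat < 2:
            raise ValueError("MRMR needs at least 2 features")
        disc = [_discretize_freq(X[:, j], self.n_bins) for j in range(n_feat)]
        log2 = np.log(2.0)
        relevance = np.array([mutual_info_score(d, y) / log2 for d in disc])
        redundancy = np.zeros((n_feat, n_feat))
        selected: list[int] = []
        scores: list[float] = []
        remaining = list(range(n_feat))
        while remaining:
            if not selected:
                objective = relevance[remaining]
            else:
                objective = np.array([
                    relevance[j] - np.mean([_pair_mi(redundancy, disc, j, s, log2)
                                            for s in selected])
                    for j in remaining])
            best = int(np.argmax(objective))  # argmax keeps first on ties
            selected.append(remaining.pop(best))
            scores.append(float(objective[best]))
        self.ranking_ = np.asarray(selected)
        self.scores_ = np.asarray(scores)
        self.relevance_ = relevance
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        k = self.n_features_in_ if self.k is None else self.k
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[:k]] = True
        return mask


def _pair_mi(cache: np.ndarray, disc, a: int, b: int, log2: float) -> float:
    if cache[a, b] == 0.0:
        cache[a, b] = cache[b, a] = mutual_info_score(disc[a], disc[b]) / log2
    return cache[a, b]


class Chi2Ranker(SelectorMixin, BaseEstimator):
    """Univariate chi-square ranking on binned features.

    Each feature is discretised (equal-width by default over its
    observed range) and scored by the Pearson chi-square statistic of
    the resulting bin-by-class contingency table; empty bins are
    dropped.  ``binning="frequency"`` switches to quantile bins, under
    which the statistic is invariant to strictly monotone feature
    transforms.
    """

    def __init__(self, n_bins: int = 10, k: int | None = None,
                 binning: str = "width"):
        self.n_bins = n_bins
        self.k = k
        self.binning = binning

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("chi-square ranking needs at least 2 classes")
        disc_fn = {"width": _discretize_width,
                   "frequency": _discretize_freq}[self.binning]
        stats = []
        for j in range(X.shape[1]):
            d = disc_fn(X[:, j], self.n_bins)
            table = pd.crosstab(d, y).to_numpy()
            table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
            if min(table.shape) < 2:
                stats.append(0.0)  # constant feature: no association
            else:
                stats.append(float(chi2_contingency(table, correction=False)[0]))
        self.scores_all_ = np.asarray(stats)
        self.ranking_ = np.argsort(-self.scores_all_, kind="stable")
        self.scores_ = self.scores_all_[self.ranking_]
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        k = self.n_features_in_ if self.k is None else self.k
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[:k]] = True
        return mask


def _as_xy(table: pd.DataFrame):
    feats = [c for c in table.columns if c not in ("source_id", "label")]
    return table[feats].to_numpy(dtype=float), table["label"].to_numpy(), feats


def mrmr_rank(table: pd.DataFrame, bins: int = 16) -> RankingResult:
    """MRMR ranking of a feature table (needs a ``label`` column)."""
    X, y, feats = _as_xy(table)
    r = MRMRRanker(n_bins=bins).fit(X, y)
    return RankingResult([feats[i] for i in r.ranking_],
                         [float(s) for s in r.scores_], "mrmr")


def chi2_rank(table: pd.DataFrame, bins: int = 10,
              binning: str = "width") -> RankingResult:
    """Chi-square ranking of a feature table (needs a ``label`` column)."""
    X, y, feats = _as_xy(table)
    r = Chi2Ranker(n_bins=bins, binning=binning).fit(X, y)
    return RankingResult([feats[i] for i in r.ranking_],
                         [float(s) for s in r.scores_], "chi2")
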