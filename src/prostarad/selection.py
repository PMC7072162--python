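"""Gain-based feature reduction: Spearman relevance + MIC redundancy.

The reduction keeps the ``k`` (default 25) top-ranked features of a table.
The first feature maximizes the absolute Spearman rank correlation with the
binary outcome; each subsequent feature f maximizes

    gain(f) = delta * |rho_s(f, y)| - (1 - delta) * mean_{s in S} MIC(f, s)

over features not yet selected, where S is the already-selected set: the
second term penalizes redundancy with what the signature already contains.
With ``delta = 1`` the procedure reduces to a pure |Spearman| ranking.

The Maximal Information Coefficient (MIC) is estimated with the MINE-style
characteristic-matrix search: over all grid shapes (p, q) with
``p * q <= n ** alpha``, one axis is equipartitioned by rank and the other
axis is partitioned optimally by dynamic programming; the normalized mutual
information ``I / log2(min(p, q))`` is maximized over shapes and over both
axis orientations.  At the cohort sizes this package targets (n of order
10^2) the DP searches every inter-point cut exactly; above ``exact_n`` the
candidate cuts are thinned to ``c * p`` rank-equipartition boundaries, the
usual MINE approximation.

:class:`GainFeatureSelector` wraps the procedure as a scikit-learn
transformer so it can sit in a Pipeline in front of the bootstrap modelling
stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data


def spearman_corr(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks.  A zero-variance input has no rank ordering;
    the correlation is defined as 0 for it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("spearman_corr expects two equal-length vectors, n >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


# --------------------------------------------------------------------------
# MIC


def _xlogx(v: np.ndarray) -> np.ndarray:
    out = np.zeros_like(v, dtype=float)
    nz = v > 0
    out[nz] = v[nz] * np.log2(v[nz])
    return out


def _equipartition(rank_order: np.ndarray, q: int, n: int) -> np.ndarray:
    """Assign each point to one of q equal-size groups by rank order."""
    groups = np.empty(n, dtype=np.intp)
    groups[rank_order] = (np.arange(n) * q) // n
    return groups


def _optimal_axis_mi(
    order_u: np.ndarray,
    rows: np.ndarray,
    q: int,
    p_max: int,
    n: int,
    exact: bool,
    c: int,
) -> np.ndarray:
    """max over partitions with <= p columns of (H_cols - H_joint) * n.

    ``order_u`` sorts points along the optimization axis; ``rows`` is the
    fixed q-row assignment.  Returns the best score for p = 2..p_max
    (index p-2), in units of n * bits.
    """
    r_sorted = rows[order_u]
    # cumulative row counts at every inter-point position 0..n
    C = np.zeros((n + 1, q))
    np.cumsum(np.eye(q)[r_sorted], axis=0, out=C[1:])
    if exact or n <= c * p_max:
        pos = np.arange(n + 1)
    else:
        pos = np.unique((np.arange(c * p_max + 1) * n) // (c * p_max))
    Cc = C[pos]  # (m, q)
    m = len(pos)
    # segment scores: sum_r n_r log2 n_r - n_col log2 n_col for every (s, t)
    diff = Cc[None, :, :] - Cc[:, None, :]  # (m, m, q), t > s meaningful
    ncol = diff.sum(axis=-1)
    seg = _xlogx(diff).sum(axis=-1) - _xlogx(ncol)
    best = np.full(p_max - 1, -np.inf)
    F = seg[0].copy()  # exactly 1 column ending at each position
    for layer in range(2, p_max + 1):
        F = np.max(F[:, None] + seg, axis=0)
        best[layer - 2] = F[-1]
        if layer > 2:
            best[layer - 2] = max(best[layer - 2], best[layer - 3])
    return best


def mic(x, y, alpha: float = 0.6, exact_n: int = 300, c: int = 15) -> float:
    """Maximal Information Coefficient of two vectors, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("mic expects two equal-length vectors")
    n = len(x)
    if n < 10:
        raise ValueError("mic requires n >= 10")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    B = max(int(np.floor(n**alpha)), 4)
    exact = n <= exact_n
    orders = (np.argsort(x, kind="stable"), np.argsort(y, kind="stable"))
    best = 0.0
    for axis in (0, 1):  # axis equipartitioned into q rows
        order_v, order_u = orders[axis], orders[1 - axis]
        for q in range(2, B // 2 + 1):
            p_max = B // q
            if p_max < 2:
                continue
            rows = _equipartition(order_v, q, n)
            counts = np.bincount(rows, minlength=q).astype(float)
            h_rows = -(_xlogx(counts / n)).sum()
            scores = _optimal_axis_mi(order_u, rows, q, p_max, n, exact, c)
            for p in range(2, p_max + 1):
                i_val = h_rows + scores[p - 2] / n
                best = max(best, i_val / np.log2(min(p, q)))
    return float(min(best, 1.0))


# --------------------------------------------------------------------------
# stepwise gain reduction


@dataclass
class ReducedFeatureSet:
    """Ordered reduced signature: feature names rank 1..k with their gains."""

    features: list[str]
    gains: list[float]
    k: int

    def to_frame(self) -> pd.DataFrame:
        parts = [f.split(".") for f in self.features]
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.features) + 1),
                "map": [p[0] if len(p) == 3 else "" for p in parts],
                "order": [p[1] if len(p) == 3 else "" for p in parts],
                "stat": [p[-1] for p in parts],
                "feature": self.features,
                "gain": self.gains,
            }
        )


class GainFeatureSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn transformer applying the Spearman + MIC gain reduction.

    Parameters
    ----------
    k : target signature size (default 25).
    delta : relevance weight in [0, 1]; 1 - delta weights the MIC redundancy
        penalty.  ``delta = 1`` is pure |Spearman| ranking.
    alpha : MIC grid-size exponent (grids limited to n ** alpha cells).
    exact_n : sample-size limit for the exact DP cut search.

    Attributes
    ----------
    selected_ : ordered list of selected column indices (rank order).
    selected_features_ : ordered list of selected column names.
    gains_ : gain value at each rank.
    """

    def __init__(self, k: int = 25, delta: float = 0.5, alpha: float = 0.6, exact_n: int = 300):
        self.k = k
        self.delta = delta
        self.alpha = alpha
        self.exact_n = exact_n

    def fit(self, X, y):
        names = list(X.columns) if hasattr(X, "columns") else None
        X = validate_data(self, X, ensure_min_samples=3)
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y have different lengths")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
        self._names = names

        n_feat = X.shape[1]
        constant = np.ptp(X, axis=0) == 0
        rel = np.array(
            [0.0 if constant[j] else abs(spearman_corr(X[:, j], y)) for j in range(n_feat)]
        )
        # lexicographic-by-name tie-break: iterate candidates in name order
        name_order = sorted(range(n_feat), key=lambda j: names[j])

        k_eff = min(self.k, n_feat)
        if self.k > n_feat:
            warnings.warn(
                f"k={self.k} exceeds the {n_feat} available features; returning all",
                stacklevel=2,
            )
        selected: list[int] = []
        gains: list[float] = []
        mic_cache: dict[tuple[int, int], float] = {}

        def redundancy(j: int) -> float:
            tot = 0.0
            for s in selected:
                key = (min(j, s), max(j, s))
                if key not in mic_cache:
                    mic_cache[key] = (
                        0.0
                        if constant[j] or constant[s]
                        else mic(X[:, j], X[:, s], self.alpha, self.exact_n)
                    )
                tot += mic_cache[key]
            return tot / len(selected)

        while len(selected) < k_eff:
            pool = [j for j in name_order if j not in selected and not constant[j]]
            if not pool:  # only constants left; spec: return them last, warn
                pool = [j for j in name_order if j not in selected]
                warnings.warn("fewer non-constant features than k", stacklevel=2)
            best_j, best_gain = None, -np.inf
            for j in pool:
                if not selected:
                    gain = rel[j] if self.delta == 0 else self.delta * rel[j]
                elif self.delta == 1.0:  # pure relevance ranking, no MIC needed
                    gain = rel[j]
                else:
                    gain = self.delta * rel[j] - (1.0 - self.delta) * redundancy(j)
                if gain > best_gain:  # strict: earlier (lex-smaller) name wins ties
                    best_j, best_gain = j, gain
            selected.append(best_j)
            gains.append(float(best_gain))

        self.selected_ = selected
        self.selected_features_ = [names[j] for j in selected]
        self.gains_ = gains
        self._mask = np.zeros(n_feat, dtype=bool)
        self._mask[selected] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self._mask

    def transform(self, X):
        """Selected columns in rank order (not original column order)."""
        check_is_fitted(self)
        if hasattr(X, "columns"):
            return X[self.selected_features_]
        X = np.asarray(X)
        return X[:, self.selected_]

    def reduced_set(self) -> ReducedFeatureSet:
        check_is_fitted(self)
        return ReducedFeatureSet(list(self.selected_features_), list(self.gains_), self.k)


def reduce_feature_set(
    table: pd.DataFrame,
    k: int = 25,
    delta: float = 0.5,
    alpha: float = 0.6,
    outcome: str = "label",
) -> ReducedFeatureSet:
    """Reduce a feature table (feature columns + binary outcome column)."""
    y = table[outcome].to_numpy()
    X = table.drop(columns=[outcome])
    sel = GainFeatureSelector(k=k, delta=delta, alpha=alpha).fit(X, y)
    return sel.reduced_set()
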