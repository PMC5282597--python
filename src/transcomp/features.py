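"""Selection of differentially favored features and empirical nulls.

Each feature column (transition or k-mer frequency) is compared between the
positive and negative group with Welch's two-sample t-test; features with
p < alpha are called favored (positive mean higher) or disfavored (lower).
Label-shuffle ensembles provide per-level null counts, and empirical
p-values follow the r/n rule: the fraction of null replicates at least as
extreme as the observed statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .transitions import FrequencyMatrix

DEFAULT_ALPHA = 0.05


def welch_statistics(pos: np.ndarray, neg: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch t-statistic, degrees of freedom and two-sided p.

    ``pos``/``neg``: (n_rows, n_features) arrays.  Columns with zero
    variance in both groups get NaN in all three outputs (untestable).
    """
    n1, n2 = pos.shape[0], neg.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 rows for Welch's test")
    m1, m2 = pos.mean(axis=0), neg.mean(axis=0)
    v1, v2 = pos.var(axis=0, ddof=1), neg.var(axis=0, ddof=1)
    a, b = v1 / n1, v2 / n2
    se2 = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    untestable = se2 == 0
    t = np.where(untestable, np.nan, t)
    df = np.where(untestable, np.nan, df)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p


@dataclass
class FeatureSelection:
    """Result of differential-feature selection.

    ``table`` has one row per feature (feature, level, t, df, p, mean_diff,
    direction) where direction is "favored", "disfavored", "ns" or
    "untestable"; ``favored``/``disfavored`` are the significant sets.
    """

    table: pd.DataFrame
    alpha: float
    favored: frozenset[str] = field(init=False)
    disfavored: frozenset[str] = field(init=False)
    untestable: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        d = self.table["direction"]
        self.favored = frozenset(self.table.index[d == "favored"])
        self.disfavored = frozenset(self.table.index[d == "disfavored"])
        self.untestable = frozenset(self.table.index[d == "untestable"])

    @property
    def selected(self) -> frozenset[str]:
        return self.favored | self.disfavored

    def direction_vector(self, feature_names: Sequence[str]) -> np.ndarray:
        """+1 for favored, -1 for disfavored, 0 otherwise, in given order."""
        out = np.zeros(len(feature_names))
        for i, f in enumerate(feature_names):
            if f in self.favored:
                out[i] = 1.0
            elif f in self.disfavored:
                out[i] = -1.0
        return out

    def counts_per_level(self, direction: str = "favored") -> pd.Series:
        sub = self.table[self.table["direction"] == direction]
        return sub.groupby("level").size()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature")


def select_features(mat: FrequencyMatrix, alpha: float = DEFAULT_ALPHA,
                    alternative: str = "two-sided") -> FeatureSelection:
    """Welch-test every feature column between the two groups.

    Favored features have p < alpha and higher mean in the positive group;
    disfavored the reverse.  Zero-variance-in-both-groups columns are
    reported as untestable.  ``alternative`` may be "two-sided" (default)
    or "one-sided" (each direction tested at its own tail).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    y = mat.y
    pos = mat.values[y == 1]
    neg = mat.values[y == 0]
    t, df, p = welch_statistics(pos, neg)
    if alternative == "one-sided":
        with np.errstate(invalid="ignore"):
            p = stats.t.sf(np.abs(t), df)
    elif alternative != "two-sided":
        raise ValueError(f"unknown alternative {alternative!r}")
    mean_diff = pos.mean(axis=0) - neg.mean(axis=0)
    direction = np.full(len(mean_diff), "ns", dtype=object)
    sig = p < alpha
    direction[np.isnan(t)] = "untestable"
    direction[sig & (mean_diff > 0)] = "favored"
    direction[sig & (mean_diff < 0)] = "disfavored"
    table = pd.DataFrame(
        {
            "level": mat.levels,
            "t": t,
            "df": df,
            "p": p,
            "mean_diff": mean_diff,
            "direction": direction,
        },
        index=pd.Index(mat.feature_names, name="feature"),
    )
    return FeatureSelection(table=table, alpha=alpha)


@dataclass
class NullSelectionEnsemble:
    """Per-level favored/disfavored counts over label-shuffle replicates.

    ``favored_counts``/``disfavored_counts``: (n_sets, n_levels) arrays,
    level L in column L-1.
    """

    favored_counts: np.ndarray
    disfavored_counts: np.ndarray
    levels: np.ndarray
    n_sets: int
    alpha: float
    seed: int

    def quartiles(self, direction: str = "favored") -> pd.DataFrame:
        counts = (self.favored_counts if direction == "favored"
                  else self.disfavored_counts)
        q1 = np.percentile(counts, 25, axis=0)
        q3 = np.percentile(counts, 75, axis=0)
        return pd.DataFrame({"level": self.levels, "Q1": q1, "Q3": q3})

    def level_p(self, observed_per_level: Sequence[int],
                direction: str = "favored") -> np.ndarray:
        """Empirical per-level p: fraction of shuffle sets with a count >=
        the observed one (the r/n rule)."""
        counts = (self.favored_counts if direction == "favored"
                  else self.disfavored_counts)
        obs = np.asarray(observed_per_level)
        return (counts >= obs[None, :]).mean(axis=0)

    def summary(self, selection: FeatureSelection | None = None) -> pd.DataFrame:
        """Quartile table in the per-level layout, with observed counts and
        empirical p-values when a selection is supplied."""
        out = self.quartiles("favored")
        if selection is not None:
            per_level = selection.counts_per_level("favored")
            obs = np.array([int(per_level.get(lv, 0)) for lv in self.levels])
            out.insert(1, "count", obs)
            out["p"] = self.level_p(obs)
        return out


def shuffle_null_selection(mat: FrequencyMatrix, n_sets: int = 1000,
                           alpha: float = DEFAULT_ALPHA, seed: int = 0
                           ) -> NullSelectionEnsemble:
    """Re-select features on label-shuffled copies of the matrix.

    Each replicate permutes the group labels (group sizes preserved) and
    repeats the Welch selection; per-level favored/disfavored counts are
    recorded.  Deterministic under ``seed``.
    """
    y = mat.y
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both groups must be present to shuffle labels")
    X = mat.values[y >= 0]
    y = y[y >= 0]
    levels = np.unique(mat.levels)
    rng = np.random.default_rng(seed)
    fav = np.zeros((n_sets, len(levels)), dtype=np.int64)
    dis = np.zeros((n_sets, len(levels)), dtype=np.int64)
    for s in range(n_sets):
        perm = rng.permutation(len(y))
        yp = y[perm]
        t, df, p = welch_statistics(X[yp == 1], X[yp == 0])
        mean_diff = X[yp == 1].mean(axis=0) - X[yp == 0].mean(axis=0)
        sig = p < alpha
        for j, lv in enumerate(levels):
            at = mat.levels == lv
            fav[s, j] = int(np.sum(sig & (mean_diff > 0) & at))
            dis[s, j] = int(np.sum(sig & (mean_diff < 0) & at))
    return NullSelectionEnsemble(fav, dis, levels, n_sets, alpha, seed)


def empirical_p(observed: float, null_values: Sequence[float],
                tail: str = "ge", add_one: bool = False) -> float:
    """Empirical p-value: fraction of null values at least as extreme.

    ``tail="ge"`` counts null >= observed, ``"le"`` counts null <= observed.
    With ``add_one`` the (r+1)/(n+1) correction is applied; the default is
    the plain r/n rule.
    """
    null = np.asarray(list(null_values), dtype=float)
    if null.size == 0:
        raise ValueError("null_values must be non-empty")
    if tail == "ge":
        r = int(np.sum(null >= observed))
    elif tail == "le":
        r = int(np.sum(null <= observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    if add_one:
        return (r + 1) / (null.size + 1)
    return r / null.size


def fisher_right_tail(a: int, b: int, c: int, d: int) -> float:
    """Right-tailed Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns P(X >= a) under the hypergeometric distribution with the
    table's margins; degenerate margins give 1.0.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be nonnegative integers")
    N = a + b + c + d
    if N == 0:
        return 1.0
    return float(stats.hypergeom.sf(a - 1, N, a + b, a + c))


class WelchFeatureSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector keeping differentially favored features.

    ``fit(X, y)`` (y binary, 1 = positive group) runs the per-column Welch
    test; ``transform`` keeps the favored plus disfavored columns, the
    feature set the downstream classifiers use as predictors.

    Fitted attributes: ``statistic_``, ``df_``, ``pvalues_``, ``mean_diff_``
    and the boolean ``support_``; ``directions_`` is +1/-1/0 per column.
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA) -> None:
        self.alpha = alpha

    def fit(self, X, y):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        t, df, p = welch_statistics(X[y == 1], X[y == 0])
        self.statistic_, self.df_, self.pvalues_ = t, df, p
        self.mean_diff_ = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        sig = p < self.alpha
        self.directions_ = np.where(
            sig & (self.mean_diff_ > 0), 1.0,
            np.where(sig & (self.mean_diff_ < 0), -1.0, 0.0),
        )
        self.support_ = self.directions_ != 0
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_
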