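"""Classification of sequences from composition features.

Implements ROC/AUC by the rank (Mann-Whitney) statistic, per-feature AUCs,
pluggable scoring backends (tree ensembles fit as regressors on 0/1
labels, following the regression-trees formulation, plus a parameter-free
consistency-score scorer), and two 10-fold cross-validation protocols:

* non_blind — features are selected once on the full data set, then the
  model is cross-validated; the selection step sees the test folds, which
  leaks information and inflates the CV AUC.
* fully_blind — feature selection is repeated inside every training fold,
  so no test-fold row ever contributes to the predictors used to score it.

Cross-species prediction trains on one matrix (selection included) and
scores another with the same feature columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold

from .features import DEFAULT_ALPHA, select_features
from .transitions import FrequencyMatrix

DEFAULT_N_TREES = 500


def roc_auc(scores: Sequence[float], labels: Sequence[int]
            ) -> tuple[float, list[tuple[float, float]]]:
    """AUC (rank statistic, ties at half weight) and the ROC curve.

    AUC = P(score_pos > score_neg) + P(tie)/2; 1.0 for a perfect ranking,
    0.5 for a random or constant one.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # ROC curve: sweep thresholds from high to low, ties collapsed
    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    ss = s[order]
    tp = np.cumsum(ys == 1)
    fp = np.cumsum(ys == 0)
    keep = np.r_[ss[1:] != ss[:-1], True]
    curve = [(0.0, 0.0)] + [
        (fp[i] / n_neg, tp[i] / n_pos) for i in np.flatnonzero(keep)
    ]
    return float(auc), curve


def per_feature_auc(mat: FrequencyMatrix) -> dict[str, float]:
    """AUC of each feature used directly as the prediction score."""
    y = mat.y
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both classes must be present")
    X = mat.values
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    aucs = (ranks[y == 1].sum(axis=0) - n_pos * (n_pos + 1) / 2) / (
        n_pos * n_neg
    )
    return dict(zip(mat.feature_names, aucs.astype(float)))


@dataclass
class ModelSpec:
    """Backend choice and hyperparameters for the scoring model.

    ``n_trees`` defaults to 500 (regression-trees ensemble size); extra
    backend keyword arguments go in ``params``.
    """

    backend: str = "random_forest"
    n_trees: int = DEFAULT_N_TREES
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class ConsistencyScorer:
    """Parameter-free scorer: sum of favored-feature frequencies minus sum
    of disfavored ones, per sequence.

    ``directions`` is +1/-1/0 per column of the (already feature-restricted)
    matrix; no model fitting is involved, which makes it a useful backend
    for isolating the effect of the CV protocol from that of the learner.
    """

    def __init__(self, directions: np.ndarray) -> None:
        self.directions = np.asarray(directions, dtype=float)

    def fit(self, X, y=None) -> "ConsistencyScorer":
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.directions


BACKENDS = ("random_forest", "gbm", "consistency")


def _make_backend(spec: ModelSpec, directions: np.ndarray | None):
    if spec.backend == "random_forest":
        return RandomForestRegressor(
            n_estimators=spec.n_trees, random_state=spec.seed, **spec.params
        )
    if spec.backend == "gbm":
        return GradientBoostingRegressor(
            n_estimators=spec.n_trees, random_state=spec.seed, **spec.params
        )
    if spec.backend == "consistency":
        if directions is None:
            raise ValueError(
                "consistency backend needs per-feature directions"
            )
        return ConsistencyScorer(directions)
    raise ValueError(
        f"unknown backend {spec.backend!r}; available: {', '.join(BACKENDS)}"
    )


def train_model(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                directions: np.ndarray | None = None):
    """Fit a scoring model on a feature-restricted matrix.

    Tree-ensemble backends are fit as regressors on the 0/1 labels and
    score with the regression output (larger = more positive); the
    consistency backend needs the selection ``directions`` instead.
    Reproducible under ``spec.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if int((y == 1).sum()) < 2 or int((y == 0).sum()) < 2:
        raise ValueError("need at least 2 rows per class to train")
    model = _make_backend(spec, directions)
    model.fit(X, y.astype(float))
    return model


@dataclass
class FoldResult:
    test_index: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    auc: float
    selected_features: frozenset[str] | None = None


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold and pooled scores/AUCs."""

    mode: str
    folds: list[FoldResult]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    pooled_auc: float
    curve: list[tuple[float, float]]
    seed: int

    @property
    def fold_aucs(self) -> list[float]:
        return [f.auc for f in self.folds]


def _scores_for(model, X: np.ndarray) -> np.ndarray:
    return np.asarray(model.predict(X), dtype=float)


def _fit_and_score(mat: FrequencyMatrix, train_idx, test_idx, alpha: float,
                   spec: ModelSpec, selection=None) -> FoldResult:
    y = mat.y
    train = mat.subset_rows(train_idx)
    if selection is None:
        selection = select_features(train, alpha)
    names = sorted(selection.selected)
    labels = y[test_idx]
    if not names:  # nothing selected: uninformative constant scores
        scores = np.zeros(len(test_idx))
    else:
        cols = [mat.data.columns.get_loc(c) for c in names]
        directions = selection.direction_vector(names)
        model = train_model(mat.values[np.ix_(train_idx, cols)], y[train_idx],
                            spec, directions=directions)
        scores = _scores_for(model, mat.values[np.ix_(test_idx, cols)])
    auc, _ = roc_auc(scores, labels)
    return FoldResult(np.asarray(test_idx), scores, labels, auc,
                      frozenset(names))


def cross_validate(mat: FrequencyMatrix, mode: str = "fully_blind",
                   k: int = 10, alpha: float = DEFAULT_ALPHA,
                   spec: ModelSpec | None = None, seed: int = 0) -> CVResult:
    """Stratified k-fold CV under the non-blind or fully blind protocol.

    non_blind selects predictors once on all rows before the folds are
    scored; fully_blind repeats predictor selection inside each training
    fold so the test fold never informs its own predictors.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if mode not in ("non_blind", "fully_blind"):
        raise ValueError(f"unknown CV mode {mode!r}")
    spec = spec or ModelSpec()
    y = mat.y
    if int((y == 1).sum()) < k or int((y == 0).sum()) < k:
        raise ValueError(f"each class needs at least k={k} rows")
    global_selection = select_features(mat, alpha) if mode == "non_blind" else None
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    for train_idx, test_idx in skf.split(mat.values, y):
        folds.append(
            _fit_and_score(mat, train_idx, test_idx, alpha, spec,
                           selection=global_selection)
        )
    order = np.concatenate([f.test_index for f in folds])
    pooled_scores = np.empty(len(y))
    pooled_scores[order] = np.concatenate([f.scores for f in folds])
    pooled_auc, curve = roc_auc(pooled_scores, y)
    return CVResult(mode=mode, folds=folds, pooled_scores=pooled_scores,
                    pooled_labels=y, pooled_auc=pooled_auc, curve=curve,
                    seed=seed)


def cross_species_predict(train_mat: FrequencyMatrix,
                          test_mat: FrequencyMatrix,
                          alpha: float = DEFAULT_ALPHA,
                          spec: ModelSpec | None = None
                          ) -> tuple[np.ndarray, float]:
    """Select features and train on one matrix, score another.

    The test matrix must carry the same feature columns (same max order);
    returns per-row scores and the AUC on the test labels.
    """
    if train_mat.feature_names != test_mat.feature_names:
        raise ValueError("train and test matrices have different columns")
    spec = spec or ModelSpec()
    selection = select_features(train_mat, alpha)
    names = sorted(selection.selected)
    if not names:
        scores = np.zeros(test_mat.shape[0])
    else:
        directions = selection.direction_vector(names)
        tr_cols = train_mat.subset_columns(names)
        te_cols = test_mat.subset_columns(names)
        model = train_model(tr_cols.values, train_mat.y, spec,
                            directions=directions)
        scores = _scores_for(model, te_cols.values)
    auc, _ = roc_auc(scores, test_mat.y)
    return scores, auc


class CompositionClassifier(BaseEstimator, ClassifierMixin):
    """Differential-feature selection plus tree-ensemble scoring, as one
    scikit-learn estimator.

    fit(X, y): Welch-select columns with p < alpha on the training data,
    then fit the backend on the selected columns.  ``decision_function``
    returns the backend score (larger = more positive);  ``predict``
    thresholds it at 0.5, matching the 0/1 regression target.
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA,
                 backend: str = "random_forest",
                 n_trees: int = DEFAULT_N_TREES, seed: int = 0) -> None:
        self.alpha = alpha
        self.backend = backend
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X, y):
        from .features import WelchFeatureSelector

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.array([0, 1])
        sel = WelchFeatureSelector(alpha=self.alpha).fit(X, y)
        self.selector_ = sel
        spec = ModelSpec(backend=self.backend, n_trees=self.n_trees,
                         seed=self.seed)
        directions = sel.directions_[sel.support_]
        if sel.support_.any():
            self.model_ = train_model(X[:, sel.support_], y, spec,
                                      directions=directions)
        else:
            self.model_ = None
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.model_ is None:
            return np.zeros(X.shape[0])
        return _scores_for(self.model_, X[:, self.selector_.support_])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)
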