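import numpy as np
import pytest
from scipy import stats

from transcomp import (ModelSpec, cross_species_predict, cross_validate,
                       frequency_matrix, per_feature_auc, roc_auc,
                       train_model)
from transcomp.classify import CompositionClassifier
from test_features import make_matrix


def brute_force_auc(scores, labels):
    """Average over all positive-negative pairs, ties at half credit."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pairs = [(a, b) for a in s[y == 1] for b in s[y == 0]]
    return np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                    for a, b in pairs])


class TestRocAuc:
    def test_perfect_and_random(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        auc, _ = roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert auc == 0.5

    def test_mixed_example(self):
        auc, _ = roc_auc([0.9, 0.8, 0.3], [1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_matches_brute_force_and_mannwhitney(self, rng):
        for _ in range(5):
            s = rng.normal(size=30)
            s[rng.random(30) < 0.3] = 0.0  # inject ties
            y = rng.integers(0, 2, size=30)
            if y.min() == y.max():
                continue
            auc, _ = roc_auc(s, y)
            assert auc == pytest.approx(brute_force_auc(s, y), abs=1e-12)
            u = stats.mannwhitneyu(s[y == 1], s[y == 0],
                                   alternative="two-sided").statistic
            assert auc == pytest.approx(
                u / ((y == 1).sum() * (y == 0).sum()), abs=1e-12
            )

    def test_curve_matches_sklearn(self, rng):
        from sklearn.metrics import roc_curve as sk_roc

        s = rng.normal(size=40)
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        _, curve = roc_auc(s, y)
        fpr, tpr, _ = sk_roc(y, s, drop_intermediate=False)
        ours = np.array(curve)
        np.testing.assert_allclose(ours[:, 0], fpr, atol=1e-12)
        np.testing.assert_allclose(ours[:, 1], tpr, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestPerFeatureAuc:
    def test_constant_feature_is_half(self, rng):
        X = np.c_[np.ones(20), rng.normal(size=20)]
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        aucs = per_feature_auc(make_matrix(X, y))
        assert aucs["f0"] == 0.5

    def test_separating_feature_is_one(self):
        X = np.c_[np.r_[np.ones(5) + 1, np.zeros(5)]]
        y = np.r_[np.ones(5), np.zeros(5)].astype(int)
        assert per_feature_auc(make_matrix(X, y))["f0"] == 1.0

    def test_columnwise_agreement_with_roc_auc(self, rng):
        X = rng.normal(size=(25, 8))
        y = rng.integers(0, 2, size=25)
        y[:2] = [0, 1]
        aucs = per_feature_auc(make_matrix(X, y))
        for j in range(8):
            ref, _ = roc_auc(X[:, j], y)
            assert aucs[f"f{j}"] == pytest.approx(ref, abs=1e-12)


class TestTrainModel:
    def test_default_spec_trees(self):
        assert ModelSpec().n_trees == 500
        with pytest.raises(ValueError):
            ModelSpec(n_trees=0)

    def test_unknown_backend_lists_available(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="random_forest"):
            train_model(X, y, ModelSpec(backend="nope"))

    def test_seed_reproducibility(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.r_[np.ones(15), np.zeros(15)].astype(int)
        spec = ModelSpec(n_trees=20, seed=5)
        m1 = train_model(X, y, spec)
        m2 = train_model(X, y, spec)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    @pytest.mark.parametrize("backend", ["random_forest", "gbm"])
    def test_separable_data_resubstitution(self, rng, backend):
        X = rng.normal(size=(60, 4))
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        X[y == 1, 0] += 3.0
        spec = ModelSpec(backend=backend, n_trees=50, seed=1)
        model = train_model(X, y, spec)
        auc, _ = roc_auc(model.predict(X), y)
        assert auc > 0.9

    def test_consistency_backend_scores(self):
        """Score is the favored-column sum minus the disfavored-column sum."""
        X = np.array([[0.2, 0.1], [0.4, 0.3], [0.0, 0.5], [0.6, 0.0]])
        y = np.array([1, 1, 0, 0])
        spec = ModelSpec(backend="consistency")
        model = train_model(X, y, spec, directions=np.array([1.0, -1.0]))
        np.testing.assert_allclose(model.predict(X), [0.1, 0.1, -0.5, 0.6])
        with pytest.raises(ValueError, match="directions"):
            train_model(X, y, spec)


class TestCrossValidate:
    def test_folds_partition_rows(self, rng):
        X = rng.normal(size=(100, 10))
        y = np.r_[np.ones(50), np.zeros(50)].astype(int)
        res = cross_validate(make_matrix(X, y), "fully_blind", k=10,
                             alpha=0.2, spec=ModelSpec("consistency"),
                             seed=0)
        seen = np.concatenate([f.test_index for f in res.folds])
        assert sorted(seen) == list(range(100))
        # stratification: 5 positives per fold +- 1
        for f in res.folds:
            assert abs(int(f.labels.sum()) - 5) <= 1

    def test_label_permuted_fully_blind_near_half(self):
        local = np.random.default_rng(1234)
        aucs = []
        for rep in range(3):
            X = local.normal(size=(80, 60))
            y = np.r_[np.ones(40), np.zeros(40)].astype(int)
            res = cross_validate(make_matrix(X, y), "fully_blind", k=10,
                                 alpha=0.05, spec=ModelSpec("consistency"),
                                 seed=rep)
            aucs.append(res.pooled_auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_leakage_inflates_non_blind(self, rng):
        """Selection leakage: non-blind pooled AUC beats fully-blind on
        noise-dominated data (mean over replicates)."""
        diffs = []
        for rep in range(6):
            X = rng.normal(size=(60, 150))
            y = np.r_[np.ones(30), np.zeros(30)].astype(int)
            mat = make_matrix(X, y)
            nb = cross_validate(mat, "non_blind", k=6, alpha=0.05,
                                spec=ModelSpec("consistency"), seed=rep)
            fb = cross_validate(mat, "fully_blind", k=6, alpha=0.05,
                                spec=ModelSpec("consistency"), seed=rep)
            diffs.append(nb.pooled_auc - fb.pooled_auc)
        assert np.mean(diffs) > 0

    def test_k_below_two_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        with pytest.raises(ValueError):
            cross_validate(make_matrix(X, y), "fully_blind", k=1)

    def test_tree_backend_on_planted_signal(self, shifted_benchmark):
        records, truth = shifted_benchmark
        mat = frequency_matrix(records[:60] + records[60:90], 5)
        spec = ModelSpec(backend="random_forest", n_trees=60, seed=0)
        res = cross_validate(mat, "fully_blind", k=5, alpha=1e-4,
                             spec=spec, seed=0)
        assert res.pooled_auc > 0.8


class TestCrossSpecies:
    def test_column_mismatch_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        a = make_matrix(X, y)
        b = make_matrix(X[:, :3], y)
        with pytest.raises(ValueError):
            cross_species_predict(a, b)

    def test_shared_signal_transfers(self, rng):
        """Shared planted features transfer across 'species'; disjoint
        ones do not."""
        def species(shared_cols, own_cols, seed):
            r = np.random.default_rng(seed)
            X = r.normal(size=(80, 100))
            y = np.r_[np.ones(40), np.zeros(40)].astype(int)
            for c in shared_cols + own_cols:
                X[y == 1, c] += 1.2
            return make_matrix(X, y)

        train = species([0, 1, 2, 3], [10, 11, 12, 13], 1)
        test_shared = species([0, 1, 2, 3], [20, 21, 22, 23], 2)
        test_disjoint = species([], [30, 31, 32, 33], 3)
        spec = ModelSpec("consistency")
        _, auc_shared = cross_species_predict(train, test_shared, 0.01, spec)
        _, auc_disjoint = cross_species_predict(train, test_disjoint, 0.01,
                                                spec)
        assert auc_shared > 0.65
        assert 0.35 <= auc_disjoint <= 0.65

    def test_resubstitution_identity(self, rng):
        X = rng.normal(size=(30, 20))
        y = np.r_[np.ones(15), np.zeros(15)].astype(int)
        X[y == 1, 0] += 2
        mat = make_matrix(X, y)
        scores, auc = cross_species_predict(mat, mat, 0.05,
                                            ModelSpec("consistency"))
        assert len(scores) == 30
        assert auc > 0.5


def test_composition_classifier_sklearn_contract(rng):
    from sklearn.base import clone
    from sklearn.model_selection import cross_val_score

    X = rng.normal(size=(60, 30))
    y = np.r_[np.ones(30), np.zeros(30)].astype(int)
    X[y == 1, 5] += 2.5
    clf = CompositionClassifier(alpha=0.05, backend="random_forest",
                                n_trees=20, seed=0)
    assert clone(clf).get_params()["n_trees"] == 20
    scores = cross_val_score(clf, X, y, cv=3)
    assert scores.mean() > 0.6
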