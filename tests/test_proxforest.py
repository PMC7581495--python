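"""Decision-path forest: activations, proximity, importance, ensemble."""

import numpy as np
import pytest

from histoprox.proxforest import (
    EnsembleModel,
    FusedRecord,
    ProximityForest,
    SchemaError,
    ensemble_predict,
    fuse,
    leaf_index,
    permutation_importance,
    predict_activations,
    proximity,
    train_forest,
    uncertainty_check,
)


def _toy_data(n=40, seed=0, informative=True):
    """Two features; class = sign of feature 0 when informative."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, 2))
    y = np.where(X[:, 0] > 0, "pos", "neg") if informative else rng.choice(["pos", "neg"], n)
    return X, y


class TestTrainForest:
    def test_separable_data_fits_perfectly(self):
        X, y = _toy_data(50)
        forest = ProximityForest(n_trees=50, seed=0).fit(X, y)
        acts = forest.predict_activations(X)
        pred = [forest.class_order[a.argmax()] for a in acts]
        assert (np.array(pred) == y).all()

    def test_seeded_determinism(self):
        X, y = _toy_data(30)
        f1 = ProximityForest(n_trees=20, seed=4).fit(X, y)
        f2 = ProximityForest(n_trees=20, seed=4).fit(X, y)
        assert np.array_equal(f1.leaf_indices(X), f2.leaf_indices(X))

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="classes"):
            ProximityForest(n_trees=5).fit(X, ["a"] * 10)

    def test_missing_tissue_trains_without_error(self, tiny_records):
        assert any(np.isnan(r.blocks["tissue10"]).any() for r in tiny_records)
        forest = train_forest(tiny_records, n_trees=20, seed=0)
        assert forest.clf is not None

    def test_schema_mismatch_names_block(self):
        rec = FusedRecord(blocks={"marker1": np.array([1.0])}, label="a")
        with pytest.raises(SchemaError, match="tissue10"):
            fuse([rec], block_names=("tissue10", "marker1"))

    def test_wrong_block_length_rejected(self):
        with pytest.raises(SchemaError, match="sift5"):
            FusedRecord(blocks={"sift5": np.zeros(4)})


class TestActivations:
    def test_vote_fractions_match_manual_recount(self):
        X, y = _toy_data(40, seed=2)
        forest = ProximityForest(n_trees=30, seed=1).fit(X, y)
        acts = forest.predict_activations(X[:5])
        # oracle: recompute votes from each tree's leaf class counts
        leaves = forest.clf.apply(X[:5])
        for i in range(5):
            votes = np.zeros(len(forest.class_order))
            for t, est in enumerate(forest.clf.estimators_):
                counts = est.tree_.value[leaves[i, t], 0, :]
                votes[counts.argmax()] += 1
            assert np.allclose(acts[i], votes / 30)

    def test_rows_sum_to_one(self):
        X, y = _toy_data(25, seed=5)
        forest = ProximityForest(n_trees=10, seed=0).fit(X, y)
        assert np.allclose(forest.predict_activations(X).sum(axis=1), 1.0)

    def test_untrained_forest_raises(self):
        with pytest.raises(RuntimeError):
            ProximityForest().predict_activations(np.zeros((1, 2)))


class TestLeafAndProximity:
    def test_leaf_matches_manual_trace_on_shallow_tree(self):
        # 4 separable points force simple splits traceable by hand
        X = np.array([[0.0], [0.1], [1.0], [1.1]])
        y = np.array(["a", "a", "b", "b"])
        forest = ProximityForest(n_trees=5, seed=0).fit(X, y)
        for t, est in enumerate(forest.clf.estimators_):
            tree = est.tree_
            for row in range(4):
                node = 0
                while tree.children_left[node] != -1:
                    go_left = X[row, tree.feature[node]] <= tree.threshold[node]
                    node = tree.children_left[node] if go_left else tree.children_right[node]
                assert leaf_index(forest, t, X[row]) == node

    def test_self_proximity_is_n_trees(self):
        X, y = _toy_data(20)
        forest = ProximityForest(n_trees=37, seed=0).fit(X, y)
        assert proximity(forest, X[3], X[3]) == 37

    def test_symmetric_and_bounded(self):
        X, y = _toy_data(30, seed=9)
        forest = ProximityForest(n_trees=25, seed=0).fit(X, y)
        rng = np.random.default_rng(1)
        for _ in range(10):
            i, j = rng.integers(0, 30, 2)
            p = proximity(forest, X[i], X[j])
            assert p == proximity(forest, X[j], X[i])
            assert 0 <= p <= 25
            assert p <= proximity(forest, X[i], X[i])

    def test_missing_value_routes_deterministically(self):
        X, y = _toy_data(40, seed=3)
        forest = ProximityForest(n_trees=10, seed=0).fit(X, y)
        q = np.array([np.nan, 0.5])
        l1 = forest.leaf_indices(q)
        l2 = forest.leaf_indices(q)
        assert np.array_equal(l1, l2)

    def test_persistence_round_trip(self, tmp_path):
        X, y = _toy_data(30)
        forest = ProximityForest(n_trees=15, seed=0).fit(X, y)
        path = tmp_path / "forest.joblib"
        forest.save(path)
        loaded = ProximityForest.load(path)
        assert np.array_equal(forest.leaf_indices(X), loaded.leaf_indices(X))
        assert loaded.class_order == forest.class_order


class TestPermutationImportance:
    @pytest.fixture(scope="class")
    def fixture_1informative(self):
        rng = np.random.default_rng(0)
        n = 200
        X = rng.normal(0, 1, (n, 5))  # col 0 informative, rest noise
        y = np.where(X[:, 0] > 0, "pos", "neg")
        X[:, 3] = 1.0  # constant column
        forest = ProximityForest(n_trees=100, seed=0).fit(X[:150], y[:150])
        return forest, X[150:], y[150:]

    def test_constant_column_has_zero_importance(self, fixture_1informative):
        forest, X, y = fixture_1informative
        dec, _ = permutation_importance(forest, X, y, 3, n_repeats=5, seed=0)
        assert dec == pytest.approx(0.0, abs=1e-12)

    def test_informative_feature_matters(self, fixture_1informative):
        forest, X, y = fixture_1informative
        dec, _ = permutation_importance(forest, X, y, 0, n_repeats=5, seed=0)
        assert dec > 0.2

    def test_noise_feature_near_zero(self, fixture_1informative):
        forest, X, y = fixture_1informative
        dec, _ = permutation_importance(forest, X, y, 2, n_repeats=5, seed=0)
        assert abs(dec) < 0.05

    def test_requires_two_repeats(self, fixture_1informative):
        forest, X, y = fixture_1informative
        with pytest.raises(ValueError):
            permutation_importance(forest, X, y, 0, n_repeats=1)


class TestEnsemble:
    def _members(self, seeds=(0, 1, 2)):
        X, y = _toy_data(40, seed=1)
        return [ProximityForest(n_trees=15, seed=s).fit(X, y) for s in seeds], X, y

    def test_mean_of_member_activations(self):
        members, X, _ = self._members()
        model = EnsembleModel(members=members)
        mean, per = ensemble_predict(model, [X[:3]] * 3)
        assert per.shape == (3, 3, 2)
        assert np.allclose(mean, per.mean(axis=0))
        assert np.allclose(mean.sum(axis=1), 1.0)

    def test_identical_members_equal_single(self):
        X, y = _toy_data(30)
        m = ProximityForest(n_trees=10, seed=0).fit(X, y)
        model = EnsembleModel(members=[m, m, m])
        mean, _ = ensemble_predict(model, [X[:2]] * 3)
        assert np.allclose(mean, m.predict_activations(X[:2]))

    def test_class_order_mismatch_rejected(self):
        X, _ = _toy_data(30)
        a = ProximityForest(n_trees=5, seed=0).fit(X, np.where(X[:, 0] > 0, "x", "y"))
        b = ProximityForest(n_trees=5, seed=0).fit(X, np.where(X[:, 0] > 0, "p", "q"))
        with pytest.raises(ValueError, match="class order"):
            EnsembleModel(members=[a, b])

    def test_unanimous_votes_are_significant(self):
        members, X, y = self._members()
        model = EnsembleModel(members=members)
        # training point deep in the "pos" region: all trees agree
        xi = X[np.argmax(X[:, 0])].reshape(1, -1)
        check = uncertainty_check(model, [xi] * 3, seed=0)
        assert check["significant"]
        assert check["interval"][0] > 0

    def test_coin_flip_votes_are_uncertain(self):
        # forest trained on pure-noise labels: activations hover near 0.5
        X, y = _toy_data(60, seed=2, informative=False)
        m = ProximityForest(n_trees=50, seed=0).fit(X, y)
        model = EnsembleModel(members=[m])
        q = np.zeros((1, 2))
        check = uncertainty_check(model, [q], seed=0)
        assert check["interval"][0] <= check["margin"] <= check["interval"][1] + 1e-9

    def test_flag_deterministic_given_seed(self):
        members, X, _ = self._members()
        model = EnsembleModel(members=members)
        q = X[5].reshape(1, -1)
        c1 = uncertainty_check(model, [q] * 3, seed=11)
        c2 = uncertainty_check(model, [q] * 3, seed=11)
        assert c1 == c2


def test_shuffled_label_forest_matches_class_prior(tiny_records):
    """Null-model calibration: training on shuffled labels yields held-out
    accuracy near the majority-class prior."""
    X, y, _, _ = fuse(tiny_records)
    rng = np.random.default_rng(0)
    y_shuf = rng.permutation(y)
    n_tr = 30
    forest = ProximityForest(n_trees=100, seed=0).fit(X[:n_tr], y_shuf[:n_tr])
    acts = forest.predict_activations(X[n_tr:])
    pred = np.array([forest.class_order[a.argmax()] for a in acts])
    acc = (pred == y[n_tr:]).mean()
    prior = max(np.bincount(np.unique(y[n_tr:], return_inverse=True)[1])) / len(y[n_tr:])
    assert abs(acc - prior) < 0.25  # small held-out set: generous sampling slack
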