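"""Proximity search, sanity flags, heatmaps and precision@k."""

import numpy as np
import pytest

from histoprox import imgprep
from histoprox.deepset import EncoderConfig, PatchEncoder
from histoprox.proxforest import ProximityForest
from histoprox.searchx import (
    QueryResult,
    build_index,
    feature_heatmap,
    precision_at_k,
    prediction_heatmap,
    query,
    sanity_flags,
)


@pytest.fixture(scope="module")
def small_index():
    rng = np.random.default_rng(0)
    X = rng.normal(0, 1, (15, 4))
    y = np.where(X[:, 0] + 0.3 * X[:, 1] > 0, "a", "b")
    forest = ProximityForest(n_trees=40, seed=0).fit(X, y)
    ids = np.array([f"rec_{i:02d}" for i in range(15)])
    index = build_index(forest, X, ids, labels=y)
    return index, X, y, ids, forest


class TestBuildIndex:
    def test_leaf_table_shape(self, small_index):
        index, X, *_ = small_index
        assert index.leaf_tables[0].shape == (15, 40)

    def test_rebuild_identical(self, small_index):
        index, X, y, ids, forest = small_index
        again = build_index(forest, X, ids, labels=y)
        assert np.array_equal(index.leaf_tables[0], again.leaf_tables[0])

    def test_rows_match_direct_leaf_calls(self, small_index):
        index, X, *_ , forest = small_index
        row = forest.leaf_indices(X[7])[0]
        assert np.array_equal(index.leaf_tables[0][7], row)


class TestQuery:
    def test_self_query_ranks_itself_first_with_max_similarity(self, small_index):
        index, X, _, ids, forest = small_index
        res = query(index, X[4], k=5, with_uncertainty=False)
        assert res.ranked[0][0] == ids[4]
        assert res.ranked[0][1] == forest.n_trees

    def test_ranking_matches_exhaustive_pairwise_oracle(self, small_index):
        index, X, _, ids, forest = small_index
        res = query(index, X[2], k=15, with_uncertainty=False)
        oracle = [forest.proximity(X[2], X[j]) for j in range(15)]
        expect = sorted(zip(ids, oracle), key=lambda t: (-t[1], t[0]))
        assert [(i, s) for i, s, _ in res.ranked] == expect

    def test_ties_broken_by_ascending_id(self, small_index):
        index, X, *_ = small_index
        res = query(index, X[0], k=15, with_uncertainty=False)
        for (ia, sa, _), (ib, sb, _) in zip(res.ranked, res.ranked[1:]):
            assert sa > sb or (sa == sb and ia < ib)

    def test_similarities_non_increasing(self, small_index):
        index, X, *_ = small_index
        res = query(index, X[9], k=10, with_uncertainty=False)
        sims = [s for _, s, _ in res.ranked]
        assert sims == sorted(sims, reverse=True)

    def test_oversized_k_warns_and_truncates(self, small_index):
        index, X, *_ = small_index
        with pytest.warns(UserWarning, match="exceeds corpus"):
            res = query(index, X[0], k=50, with_uncertainty=False)
        assert len(res.ranked) == 15

    def test_exclude_id_removes_self(self, small_index):
        index, X, _, ids, _ = small_index
        res = query(index, X[4], k=15, exclude_id=ids[4], with_uncertainty=False)
        assert ids[4] not in res.top_ids()

    def test_removing_record_preserves_relative_order(self, small_index):
        index, X, _, ids, _ = small_index
        full = query(index, X[3], k=15, with_uncertainty=False).top_ids()
        drop = full[5]
        reduced = query(index, X[3], k=15, exclude_id=drop, with_uncertainty=False).top_ids()
        assert reduced == [i for i in full if i != drop]


class TestSanityFlags:
    def test_matching_expected_label_all_clear(self, small_index):
        *_, forest = small_index
        index, X, y, ids, _ = small_index
        i = 0
        flags = sanity_flags(forest, X[i], expected_label=y[i], with_uncertainty=False)
        assert flags["prediction_check_flag"] is False

    def test_mismatched_expected_label_raises_flag(self, small_index):
        index, X, y, ids, forest = small_index
        wrong = "b" if y[0] == "a" else "a"
        flags = sanity_flags(forest, X[0], expected_label=wrong, with_uncertainty=False)
        assert flags["prediction_check_flag"] is True

    def test_near_uniform_activations_flag_uncertain(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (60, 3))
        y = rng.choice(["a", "b", "c"], 60)  # pure noise labels
        forest = ProximityForest(n_trees=60, seed=0).fit(X, y)
        flags = sanity_flags(forest, np.zeros(3), seed=0)
        assert flags["uncertainty_flag"] is True


@pytest.fixture(scope="module")
def encoder_and_std():
    enc = PatchEncoder(
        class_order=("nontumor", "low_grade", "malignant"),
        config=EncoderConfig(seed=0),
    )
    rng = np.random.default_rng(2)
    img = rng.integers(0, 255, (512, 700, 3)).astype(np.uint8)
    return enc, imgprep.standardize(img)


class TestHeatmaps:
    def test_per_tile_class_activations_sum_to_one(self, encoder_and_std):
        enc, std = encoder_and_std
        hm = prediction_heatmap(enc, std)
        total = sum(hm.grids[c] for c in enc.class_order)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_exactly_four_imputed_tiles(self, encoder_and_std):
        enc, std = encoder_and_std
        hm = prediction_heatmap(enc, std)
        assert hm.imputed_mask.sum() == 4

    def test_constant_image_gives_uniform_grids(self):
        enc = PatchEncoder(class_order=("a", "b", "c"))
        std = imgprep.standardize(np.full((512, 512, 3), 150, dtype=np.uint8))
        hm = prediction_heatmap(enc, std)
        for grid in hm.grids.values():
            assert np.allclose(grid, grid[0, 0], atol=1e-12)

    def test_feature_heatmap_bounded_and_constant_on_constant(self):
        enc = PatchEncoder(class_order=("a", "b"))
        std = imgprep.standardize(np.full((512, 512, 3), 90, dtype=np.uint8))
        grid = feature_heatmap(enc, std, 17)
        assert np.allclose(grid, grid[0, 0], atol=1e-12)
        assert (grid >= 0).all() and (grid <= 1).all()

    def test_feature_index_out_of_range(self, encoder_and_std):
        enc, std = encoder_and_std
        with pytest.raises(ValueError):
            feature_heatmap(enc, std, 100)

    def test_some_deep_feature_grid_tracks_prediction_grid(self):
        """After training, the class head reads the 100 deep features, so at
        least one feature's spatial grid must correlate with the majority
        class's prediction grid on a spatially heterogeneous image."""
        from histoprox.deepset import EncoderConfig, train_encoder

        rng = np.random.default_rng(0)
        patches, labels = [], []
        for cls, period in (("a", 48), ("b", 8)):
            for _ in range(10):
                base = np.indices((224, 224)).sum(axis=0) // period % 2
                img = (base * 150 + 50 + rng.normal(0, 6, (224, 224)))[..., None]
                patches.append(np.clip(np.repeat(img, 3, 2), 0, 255).astype(np.uint8))
                labels.append(cls)
        enc = train_encoder(patches, labels, config=EncoderConfig(seed=0, epochs=6))

        # composite image: coarse texture left, fine texture right
        big = np.zeros((512, 512, 3), dtype=np.uint8)
        coarse = np.indices((512, 256)).sum(axis=0) // 48 % 2
        fine = np.indices((512, 256)).sum(axis=0) // 8 % 2
        big[:, :256] = (coarse * 150 + 50)[..., None]
        big[:, 256:] = (fine * 150 + 50)[..., None]
        std = imgprep.StandardImage(full=big, crop512=big, source_id="mix")

        hm = prediction_heatmap(enc, std)
        majority = max(hm.grids, key=lambda c: hm.grids[c].sum())
        pred_grid = hm.grids[majority].ravel()
        if np.std(pred_grid) < 1e-9:
            pytest.skip("degenerate prediction grid")
        grids = [feature_heatmap(enc, std, f).ravel() for f in range(100)]
        best = max(
            abs(np.corrcoef(g, pred_grid)[0, 1]) for g in grids if np.std(g) > 1e-12
        )
        assert best > 0.5


class TestPrecisionAtK:
    def _result(self, ids):
        return QueryResult(
            ranked=[(i, 10 - n, (10 - n) / 10) for n, i in enumerate(ids)],
            prediction=np.array([1.0, 0.0]),
            class_order=("a", "b"),
        )

    def test_all_match(self):
        res = self._result(["r1", "r2", "r3"])
        labels = {"r1": "a", "r2": "a", "r3": "a"}
        assert precision_at_k(res, "a", labels, 3) == 1.0

    def test_five_of_eight(self):
        ids = [f"r{i}" for i in range(8)]
        labels = {f"r{i}": ("a" if i < 5 else "b") for i in range(8)}
        assert precision_at_k(self._result(ids), "a", labels, 8) == pytest.approx(0.625)

    def test_none_match(self):
        res = self._result(["r1", "r2"])
        assert precision_at_k(res, "a", {"r1": "b", "r2": "b"}, 2) == 0.0

    def test_k_beyond_results_warns(self):
        res = self._result(["r1"])
        with pytest.warns(UserWarning):
            assert precision_at_k(res, "a", {"r1": "a"}, 5) == 1.0
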