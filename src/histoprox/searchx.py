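"""Similarity search over a corpus using forest decision-path proximity.

A query is routed through every tree of the (possibly ensembled) forest;
corpus records sharing its leaf in a tree gain one similarity point, and
the corpus is returned ranked by total similarity.  Each result carries
three sanity checks: (i) bootstrap prediction uncertainty, (ii) the class
prediction itself as a plausibility check against a caller-supplied label,
and (iii) a 5x5 prediction heatmap for human review.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imgprep import DROPPED_SLOTS, GRID, PATCH, StandardImage, grid_offsets
from .proxforest import EnsembleModel, ensemble_predict, predict_activations, uncertainty_check


def _members(model):
    return model.members if isinstance(model, EnsembleModel) else [model]


@dataclass
class SearchIndex:
    """Precomputed per-tree leaf ids of every corpus record (per member)."""

    model: object  # ProximityForest or EnsembleModel
    ids: np.ndarray
    labels: np.ndarray
    leaf_tables: list  # one (n_records, n_trees) table per member

    @property
    def n_records(self) -> int:
        return len(self.ids)


def build_index(model, corpus_inputs, ids, labels=None) -> SearchIndex:
    """Precompute leaf tables so query cost does not involve re-traversing
    trees for the corpus side.

    ``corpus_inputs`` is one feature matrix, or a list of matrices (one per
    ensemble member) when members consume different blocks.
    """
    members = _members(model)
    if not isinstance(corpus_inputs, (list, tuple)):
        corpus_inputs = [corpus_inputs] * len(members)
    tables = [m.leaf_indices(X) for m, X in zip(members, corpus_inputs)]
    n = tables[0].shape[0]
    ids = np.asarray(ids)
    if len(ids) != n:
        raise ValueError("ids length does not match corpus size")
    labels = np.asarray(labels) if labels is not None else np.full(n, None)
    return SearchIndex(model=model, ids=ids, labels=labels, leaf_tables=tables)


@dataclass
class QueryResult:
    """Ranked corpus ids with similarity counts, prediction and flags."""

    ranked: list  # (corpus id, similarity count, normalized similarity)
    prediction: np.ndarray
    class_order: tuple
    flags: dict = field(default_factory=dict)

    def top_ids(self, k: int | None = None):
        return [r[0] for r in (self.ranked if k is None else self.ranked[:k])]


def query(
    index: SearchIndex,
    xs,
    k: int = 10,
    exclude_id=None,
    expected_label=None,
    with_uncertainty: bool = True,
    seed: int = 0,
) -> QueryResult:
    """Rank the corpus by proximity to the query.

    Ties are broken by ascending corpus id; when the query is a corpus
    record its own id can be excluded via ``exclude_id`` (leave-one-out
    evaluation).  ``xs`` is a single feature vector or a per-member list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    members = _members(index.model)
    if not isinstance(xs, (list, tuple)):
        xs = [xs] * len(members)
    sims = np.zeros(index.n_records, dtype=np.int64)
    for m, x, table in zip(members, xs, index.leaf_tables):
        leaves = m.leaf_indices(x)[0]
        sims += (table == leaves[None, :]).sum(axis=1)
    total_trees = sum(m.n_trees for m in members)

    mask = np.ones(index.n_records, dtype=bool)
    if exclude_id is not None:
        mask &= index.ids != exclude_id
    order = np.lexsort((index.ids[mask], -sims[mask]))
    avail = int(mask.sum())
    if k > avail:
        warnings.warn(f"k={k} exceeds corpus size {avail}; truncating")
        k = avail
    sel_ids = index.ids[mask][order][:k]
    sel_sims = sims[mask][order][:k]
    ranked = [(i, int(s), s / total_trees) for i, s in zip(sel_ids, sel_sims)]

    if isinstance(index.model, EnsembleModel):
        prediction, _ = ensemble_predict(index.model, xs)
        prediction = prediction[0]
    else:
        prediction = predict_activations(index.model, xs[0])
        if prediction.ndim == 2:
            prediction = prediction[0]
    flags = sanity_flags(
        index.model, xs, expected_label=expected_label,
        with_uncertainty=with_uncertainty, seed=seed,
    )
    return QueryResult(
        ranked=ranked,
        prediction=prediction,
        class_order=tuple(members[0].class_order),
        flags=flags,
    )


def sanity_flags(
    model,
    xs,
    expected_label=None,
    heatmap=None,
    with_uncertainty: bool = True,
    level: float = 0.05,
    seed: int = 0,
) -> dict:
    """The three search sanity checks; any raised flag means the search
    results for this query should not be trusted as-is."""
    members = _members(model)
    if not isinstance(xs, (list, tuple)):
        xs = [xs] * len(members)
    if isinstance(model, EnsembleModel):
        mean_act, _ = ensemble_predict(model, xs)
        mean_act = mean_act[0] if mean_act.ndim == 2 else mean_act
        ens = model
    else:
        mean_act = predict_activations(model, xs[0])
        if mean_act.ndim == 2:
            mean_act = mean_act[0]
        ens = EnsembleModel(members=[model])
    flags = {"uncertainty_flag": False, "prediction_check_flag": False,
             "heatmap_available": heatmap is not None}
    if with_uncertainty:
        # bootstrap inputs must be single records
        singles = [np.asarray(x, dtype=np.float64).reshape(1, -1) for x in xs]
        check = uncertainty_check(ens, singles, level=level, seed=seed)
        flags["uncertainty_flag"] = not check["significant"]
        flags["uncertainty"] = check
    if expected_label is not None:
        predicted = members[0].class_order[int(np.argmax(mean_act))]
        flags["prediction_check_flag"] = predicted != expected_label
    return flags


# ---------------------------------------------------------------------------
# heatmaps
# ---------------------------------------------------------------------------


@dataclass
class Heatmap:
    """Per-class 5x5 activation grids; 4 tiles imputed from their nearest
    evaluated neighbours.  Per-tile class values sum to 1."""

    grids: dict  # class -> (5, 5) array
    imputed_mask: np.ndarray  # (5, 5) bool, exactly 4 True


def _evaluated_slots():
    return [(i, j) for i in range(GRID) for j in range(GRID) if (i, j) not in DROPPED_SLOTS]


def _impute_sources(slot):
    """4 nearest evaluated tiles by Euclidean grid distance, row-major
    tie-break."""
    cands = sorted(
        _evaluated_slots(),
        key=lambda s: ((s[0] - slot[0]) ** 2 + (s[1] - slot[1]) ** 2, s[0], s[1]),
    )
    return cands[:4]


def _tile_values(encoder, std: StandardImage, fn):
    h, w = std.full.shape[:2]
    offs = grid_offsets(h, w)
    vals = {}
    for i, j in _evaluated_slots():
        r, c = offs[i, j]
        patch = std.full[r : r + PATCH, c : c + PATCH]
        vals[(i, j)] = fn(patch)
    return vals


def prediction_heatmap(encoder, std: StandardImage, covariates=None) -> Heatmap:
    """Class-activation heatmap over the 5x5 patch grid.

    The 21 evaluated tiles get the encoder's softmax activations; the 4
    non-evaluated tiles are imputed per class with the median of their four
    nearest evaluated tiles, then renormalized so every tile's class values
    sum to 1."""
    classes = encoder.class_order
    vals = _tile_values(
        encoder, std, lambda p: encoder.class_activations(p, covariates)
    )
    grids = {cls: np.zeros((GRID, GRID)) for cls in classes}
    mask = np.zeros((GRID, GRID), dtype=bool)
    for (i, j), act in vals.items():
        for c, cls in enumerate(classes):
            grids[cls][i, j] = act[c]
    for slot in DROPPED_SLOTS:
        mask[slot] = True
        sources = _impute_sources(slot)
        tile = np.array(
            [np.median([vals[s][c] for s in sources]) for c in range(len(classes))]
        )
        tile = tile / tile.sum()
        for c, cls in enumerate(classes):
            grids[cls][slot] = tile[c]
    return Heatmap(grids=grids, imputed_mask=mask)


def feature_heatmap(encoder, std: StandardImage, feature_idx: int) -> np.ndarray:
    """5x5 grid of one deep-head feature, same grid and imputation as the
    prediction heatmap, without renormalization."""
    if not 0 <= feature_idx < 100:
        raise ValueError("feature_idx must be in 0..99")
    vals = _tile_values(encoder, std, lambda p: float(encoder.encode(p)[feature_idx]))
    grid = np.zeros((GRID, GRID))
    for (i, j), v in vals.items():
        grid[i, j] = v
    for slot in DROPPED_SLOTS:
        grid[slot] = np.median([vals[s] for s in _impute_sources(slot)])
    return grid


def precision_at_k(result: QueryResult, query_label, corpus_labels: dict, k: int):
    """Fraction of the top-k results whose label matches the query label;
    computed over the available results (with a warning) when k exceeds
    them."""
    ranked = result.ranked
    if k > len(ranked):
        warnings.warn(f"k={k} exceeds available results ({len(ranked)})")
        k = len(ranked)
    if k == 0:
        return 0.0
    hits = sum(1 for rid, *_ in ranked[:k] if corpus_labels[rid] == query_label)
    return hits / k
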