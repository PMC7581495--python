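"""Random Forest with exposed decision paths.

The disease-state classifier doubles as a similarity metric: two records
that traverse the identical sequence of decisions in a tree land in the same
leaf, and each such tree increments their similarity by one, giving a
proximity in 0..n_trees (1000 by default).  This module wraps a
scikit-learn forest, exposing per-tree leaf identities, vote-fraction class
activations, block-aware permutation importance, a 3-member ensemble and a
bootstrap-over-trees uncertainty check.

Missing clinical covariates are passed as NaN; routing of missing values is
deterministic (a fixed per-split direction — the majority branch when the
split saw no missing values during training), which keeps "identical
decision sequence" well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

DEFAULT_N_TREES = 1000

#: canonical feature blocks and their lengths
BLOCK_DIMS = {
    "hand2412": 2412,
    "deepset100": 100,
    "generic2048": 2048,
    "sift5": 5,
    "tissue10": 10,
    "marker1": 1,
}


class SchemaError(ValueError):
    """Feature-block schema mismatch; message names the offending block."""


@dataclass
class FusedRecord:
    """One case's concatenated feature blocks plus label and group id.

    Blocks are optional per configuration; a present block must have its
    declared length.  Missing tissue is NaN-encoded inside ``tissue10``
    (the forest consumes NaN; neural consumers get zeros upstream).
    """

    blocks: dict
    label: object = None
    group_id: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        for name, vec in self.blocks.items():
            if name not in BLOCK_DIMS:
                raise SchemaError(f"unknown feature block {name!r}")
            vec = np.asarray(vec, dtype=np.float64)
            if vec.shape != (BLOCK_DIMS[name],):
                raise SchemaError(
                    f"block {name!r} has length {vec.size}, expected {BLOCK_DIMS[name]}"
                )
            self.blocks[name] = vec


def block_slices(block_names) -> dict:
    """name -> column slice of the fused matrix for the given block order."""
    out = {}
    pos = 0
    for name in block_names:
        out[name] = slice(pos, pos + BLOCK_DIMS[name])
        pos += BLOCK_DIMS[name]
    return out


def fuse(records, block_names=None):
    """Stack records into a (n, d) matrix; returns (X, y, groups, ids)."""
    records = list(records)
    if not records:
        raise SchemaError("no records")
    if block_names is None:
        block_names = tuple(records[0].blocks)
    rows = []
    for rec in records:
        parts = []
        for name in block_names:
            if name not in rec.blocks:
                raise SchemaError(f"record {rec.record_id!r} missing block {name!r}")
            parts.append(rec.blocks[name])
        rows.append(np.concatenate(parts))
    X = np.vstack(rows)
    y = np.array([r.label for r in records])
    groups = np.array([r.group_id for r in records])
    ids = np.array([r.record_id for r in records])
    return X, y, groups, ids


class ProximityForest:
    """1000-tree Random Forest exposing leaf identities for proximity."""

    def __init__(
        self,
        n_trees: int = DEFAULT_N_TREES,
        seed: int = 0,
        block_names=None,
    ) -> None:
        self.n_trees = n_trees
        self.seed = seed
        self.block_names = tuple(block_names) if block_names else None
        self.clf: RandomForestClassifier | None = None
        self.class_order: tuple = ()

    # -- training ---------------------------------------------------------
    def fit(self, X: np.ndarray, y) -> "ProximityForest":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes")
        self.clf = RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion="gini",
            max_features="sqrt",
            bootstrap=True,
            min_samples_leaf=1,
            random_state=self.seed,
            n_jobs=1,
        )
        self.clf.fit(np.asarray(X, dtype=np.float64), y)
        self.class_order = tuple(self.clf.classes_)
        return self

    def _check_trained(self) -> None:
        if self.clf is None:
            raise RuntimeError("forest is not trained")

    def _as_matrix(self, x) -> np.ndarray:
        if isinstance(x, FusedRecord):
            x, *_ = fuse([x], self.block_names)
        x = np.asarray(x, dtype=np.float64)
        return x.reshape(1, -1) if x.ndim == 1 else x

    # -- decision paths ---------------------------------------------------
    def leaf_indices(self, x) -> np.ndarray:
        """(n, n_trees) leaf identifier of every record in every tree —
        a total deterministic function of the record."""
        self._check_trained()
        return self.clf.apply(self._as_matrix(x))

    def tree_votes(self, x) -> np.ndarray:
        """(n, n_trees) per-tree predicted class index (argmax of the leaf
        class counts, ties to the lower index)."""
        self._check_trained()
        leaves = self.leaf_indices(x)
        votes = np.empty_like(leaves)
        for t, est in enumerate(self.clf.estimators_):
            values = est.tree_.value[leaves[:, t], 0, :]
            votes[:, t] = values.argmax(axis=1)
        return votes

    def predict_activations(self, x) -> np.ndarray:
        """Fraction of trees voting each class; rows are on the simplex."""
        votes = self.tree_votes(x)
        n, _ = votes.shape
        acts = np.zeros((n, len(self.class_order)))
        for i in range(n):
            acts[i] = np.bincount(votes[i], minlength=len(self.class_order))
        acts /= self.n_trees
        return acts

    def proximity(self, a, b) -> int:
        """Number of trees in which a and b share a leaf (identical decision
        sequence); symmetric, in [0, n_trees], and n_trees at identity."""
        la = self.leaf_indices(a)[0]
        lb = self.leaf_indices(b)[0]
        return int((la == lb).sum())

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        self._check_trained()
        joblib.dump(
            {
                "clf": self.clf,
                "n_trees": self.n_trees,
                "seed": self.seed,
                "block_names": self.block_names,
                "class_order": self.class_order,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "ProximityForest":
        blob = joblib.load(path)
        forest = cls(blob["n_trees"], blob["seed"], blob["block_names"])
        forest.clf = blob["clf"]
        forest.class_order = blob["class_order"]
        return forest


def train_forest(
    records,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    block_names=None,
) -> ProximityForest:
    """Fit a proximity forest on fused records (labels from the records)."""
    X, y, *_ = fuse(records, block_names)
    block_names = block_names or tuple(records[0].blocks)
    forest = ProximityForest(n_trees=n_trees, seed=seed, block_names=tuple(block_names))
    return forest.fit(X, y)


def predict_activations(forest: ProximityForest, x) -> np.ndarray:
    acts = forest.predict_activations(x)
    return acts[0] if (isinstance(x, FusedRecord) or np.asarray(x).ndim == 1) else acts


def leaf_index(forest: ProximityForest, tree: int, x) -> int:
    """Leaf identifier of one record in one tree."""
    return int(forest.leaf_indices(x)[0, tree])


def proximity(forest: ProximityForest, a, b) -> int:
    return forest.proximity(a, b)


def permutation_importance(
    forest: ProximityForest,
    X: np.ndarray,
    y,
    target,
    n_repeats: int = 10,
    seed: int = 0,
    columns=None,
):
    """Mean decrease in held-out accuracy when the target feature (or block)
    is shuffled.

    ``target`` is a column index, or a block name when the forest was
    trained on named blocks (the 10 tissue one-hot columns are shuffled
    jointly as one block).  Returns (mean_decrease, std).
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    forest._check_trained()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if columns is not None:
        cols = np.asarray(columns)
    elif isinstance(target, str):
        if forest.block_names is None:
            raise SchemaError("forest has no named blocks")
        sl = block_slices(forest.block_names)[target]
        cols = np.arange(sl.start, sl.stop)
    else:
        cols = np.array([int(target)])
    votes = forest.tree_votes(X)
    base_pred = np.array(
        [forest.class_order[np.bincount(v, minlength=len(forest.class_order)).argmax()] for v in votes]
    )
    baseline = float((base_pred == y).mean())
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_repeats):
        Xs = X.copy()
        perm = rng.permutation(len(X))
        Xs[:, cols] = Xs[perm][:, cols]
        pred = np.array(
            [
                forest.class_order[
                    np.bincount(v, minlength=len(forest.class_order)).argmax()
                ]
                for v in forest.tree_votes(Xs)
            ]
        )
        accs.append(float((pred == y).mean()))
    accs = np.asarray(accs)
    return baseline - accs.mean(), accs.std()


@dataclass
class EnsembleModel:
    """Three proximity forests, each paired with an independently seeded
    encoder feature block; predictions are averaged, and the per-member
    spread feeds the uncertainty check."""

    members: list

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty ensemble")
        orders = {m.class_order for m in self.members}
        if len(orders) != 1:
            raise ValueError("ensemble members disagree on class order")

    @property
    def class_order(self):
        return self.members[0].class_order

    @property
    def n_trees(self):
        return sum(m.n_trees for m in self.members)


def ensemble_predict(model: EnsembleModel, xs):
    """Mean of member activations; per-member activations retained.

    ``xs`` is a list with one input per member (members may consume
    different feature blocks); pass the same object repeated when members
    share a schema.
    """
    per_member = np.stack(
        [predict_activations(m, x) for m, x in zip(model.members, xs)]
    )
    return per_member.mean(axis=0), per_member


def uncertainty_check(
    model: EnsembleModel,
    xs,
    level: float = 0.05,
    n_boot: int = 200,
    seed: int = 0,
):
    """Bootstrap trees within each member to test whether the top-class
    margin (top minus runner-up activation) is significantly above zero.

    Returns ``{"significant": bool, "interval": (lo, hi), "margin": float}``;
    the prediction is "uncertain" when the interval includes 0.
    """
    mean_act, _ = ensemble_predict(model, xs)
    if mean_act.ndim == 2:
        mean_act = mean_act[0]
    order = np.argsort(-mean_act, kind="stable")
    top, runner = order[0], order[1]
    member_votes = [m.tree_votes(x)[0] for m, x in zip(model.members, xs)]
    k = len(model.class_order)
    rng = np.random.default_rng(seed)
    margins = np.empty(n_boot)
    for b in range(n_boot):
        acts = np.zeros(k)
        for votes in member_votes:
            sample = votes[rng.integers(0, len(votes), len(votes))]
            acts += np.bincount(sample, minlength=k) / len(votes)
        acts /= len(member_votes)
        margins[b] = acts[top] - acts[runner]
    lo, hi = np.percentile(margins, [100 * level / 2, 100 * (1 - level / 2)])
    margin = float(mean_act[top] - mean_act[runner])
    return {"significant": bool(lo > 0), "interval": (float(lo), float(hi)), "margin": margin}
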