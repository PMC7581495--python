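"""Evaluation protocol: ten-fold and leave-one-pathologist-out
cross-validation, count-weighted multiclass AUROC, precision@k curves, the
label-shuffled permutation null, and two-tailed rank-sum comparison of
replicate sets.

Leave-one-pathologist-out (LOPO) evaluation holds out every case of one
contributor at a time, so contributor-specific staining/camera artifacts
can never leak from training corpus to query set; anything fitted on
training data (forest, SIFT vocabulary, encoder) is refitted inside each
fold via the ``refit`` hook.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .proxforest import ProximityForest, fuse
from .searchx import build_index, precision_at_k, query

DEFAULT_KS = tuple(range(1, 11))


# ---------------------------------------------------------------------------
# task and method registries
# ---------------------------------------------------------------------------

def _label_he_vs_others(gold: dict):
    if gold.get("stain") in (None, "MISSING"):
        return None
    return "HE" if gold["stain"] == "HE" else "other"


def _label_he_vs_ihc(gold: dict):
    return gold["stain"] if gold.get("stain") in ("HE", "IHC") else None


#: task name -> function(gold label dict) -> task label, or None to exclude
TASKS = {
    "he_vs_others": _label_he_vs_others,
    "he_vs_ihc": _label_he_vs_ihc,
    "tissue10": lambda g: g.get("tissue") if g.get("tissue") not in (None, "MISSING") else None,
    "disease3": lambda g: g.get("disease") if g.get("disease") not in (None, "MISSING") else None,
}

#: the search/classification method ladder: feature blocks + ensemble size
METHODS = {
    "method_i": {"blocks": ("hand2412",), "n_members": 1},
    "method_ii": {"blocks": ("hand2412", "tissue10"), "n_members": 1},
    "method_iii": {"blocks": ("hand2412", "tissue10", "marker1"), "n_members": 1},
    "method_iv": {"blocks": ("hand2412", "tissue10", "marker1", "sift5"), "n_members": 1},
    "method_v": {"blocks": ("generic2048",), "n_members": 1},
    "method_vi": {"blocks": ("deepset100",), "n_members": 1},
    "method_vii": {"blocks": ("deepset100",), "n_members": 1},
    "method_viii": {"blocks": ("hand2412", "deepset100"), "n_members": 1},
    "method_ix": {"blocks": ("hand2412", "deepset100", "tissue10"), "n_members": 1},
    "method_x": {"blocks": ("hand2412", "generic2048", "tissue10"), "n_members": 1},
    "method_xi": {"blocks": ("hand2412", "deepset100", "generic2048", "tissue10"), "n_members": 1},
    "method_xii": {"blocks": ("hand2412", "deepset100", "tissue10"), "n_members": 3},
    "method_xiii": {"blocks": ("hand2412", "deepset100", "generic2048", "tissue10"), "n_members": 3},
    "method_xiv": {"blocks": ("hand2412", "deepset100", "tissue10", "marker1"), "n_members": 3},
    "method_xv": {"blocks": ("hand2412", "deepset100", "tissue10", "marker1", "sift5"), "n_members": 3},
}


@dataclass
class EvalReport:
    task: str
    n_records: int
    class_order: tuple = ()
    per_class: list = field(default_factory=list)  # {label, auroc, count}
    overall_auroc: float | None = None
    auroc_replicates: list = field(default_factory=list)
    precision_at_k: dict = field(default_factory=dict)  # k -> value
    precision_replicates: dict = field(default_factory=dict)  # k -> [per-replicate]
    per_group: dict = field(default_factory=dict)  # group -> {k: value}
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=float, indent=2)


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def weighted_auroc(per_class) -> float:
    """Count-weighted mean of per-class AUROCs: sum(count_c * auroc_c) /
    sum(count_c)."""
    per_class = list(per_class)
    if not per_class:
        raise ValueError("empty per-class list")
    aurocs = np.array([a for a, _ in per_class], dtype=np.float64)
    counts = np.array([c for _, c in per_class], dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError("class counts must be > 0")
    return float((aurocs * counts).sum() / counts.sum())


def multiclass_weighted_auroc(y, scores, class_order):
    """One-vs-rest AUROC per class (rank statistic) and the count-weighted
    overall value.  Returns (overall, per_class list of dicts)."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=np.float64)
    per_class = []
    pairs = []
    for c, cls in enumerate(class_order):
        pos = y == cls
        count = int(pos.sum())
        if count == 0 or count == len(y):
            continue
        auroc = float(roc_auc_score(pos.astype(int), scores[:, c]))
        per_class.append({"label": cls, "auroc": auroc, "count": count})
        pairs.append((auroc, count))
    return weighted_auroc(pairs), per_class


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _drop_rare_classes(records, min_count: int = 2):
    labels, counts = np.unique([r.label for r in records], return_counts=True)
    rare = set(labels[counts < min_count])
    if rare:
        warnings.warn(f"excluding classes with < {min_count} records: {sorted(rare)}")
    return [r for r in records if r.label not in rare]


def kfold_replicates(
    records,
    task: str = "",
    n_folds: int = 10,
    n_replicates: int = 10,
    seeds=None,
    n_trees: int = 1000,
    block_names=None,
) -> EvalReport:
    """Stratified k-fold cross-validation repeated over seeded replicates
    (seeds 0..n_replicates-1 by default); reports mean and spread of the
    count-weighted AUROC over replicates."""
    records = _drop_rare_classes(list(records))
    seeds = list(seeds) if seeds is not None else list(range(n_replicates))
    X, y, _, _ = fuse(records, block_names)
    block_names = block_names or tuple(records[0].blocks)
    class_order = tuple(sorted(set(y)))

    auroc_reps = []
    last_per_class = []
    for seed in seeds:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        scores = np.zeros((len(y), len(class_order)))
        for train_idx, test_idx in skf.split(X, y):
            forest = ProximityForest(n_trees=n_trees, seed=seed, block_names=block_names)
            forest.fit(X[train_idx], y[train_idx])
            acts = forest.predict_activations(X[test_idx])
            for c, cls in enumerate(class_order):
                if cls in forest.class_order:
                    scores[test_idx, c] = acts[:, forest.class_order.index(cls)]
        overall, per_class = multiclass_weighted_auroc(y, scores, class_order)
        auroc_reps.append(overall)
        last_per_class = per_class
    return EvalReport(
        task=task,
        n_records=len(records),
        class_order=class_order,
        per_class=last_per_class,
        overall_auroc=float(np.mean(auroc_reps)),
        auroc_replicates=auroc_reps,
        extras={"auroc_std": float(np.std(auroc_reps)), "n_folds": n_folds},
    )


def lopo_cv(
    records,
    task: str = "",
    n_trees: int = 1000,
    seed: int = 0,
    block_names=None,
    ks=DEFAULT_KS,
    refit=None,
    shuffle_training_labels: bool = False,
) -> EvalReport:
    """Leave-one-pathologist-out search evaluation.

    For each group g: fit the forest on every record with group != g
    (optionally after a ``refit(train, test)`` hook that re-derives any
    fold-fitted feature blocks such as the SIFT vocabulary or encoder),
    index the training corpus, and query each held-out record against it;
    precision@k is aggregated overall and per group.  With
    ``shuffle_training_labels`` the training labels are permuted (seeded)
    before fitting while evaluation labels stay untouched — the
    permutation-test null of search.
    """
    records = list(records)
    groups = sorted({r.group_id for r in records})
    if len(groups) < 2:
        raise ValueError("leave-one-pathologist-out needs >= 2 distinct groups")
    block_names = block_names or tuple(records[0].blocks)
    rng = np.random.default_rng(seed)

    per_query = {k: [] for k in ks}
    per_group: dict = {}
    for g in groups:
        train = [r for r in records if r.group_id != g]
        test = [r for r in records if r.group_id == g]
        if refit is not None:
            train, test = refit(train, test)
        X_tr, y_tr, _, ids_tr = fuse(train, block_names)
        y_fit = rng.permutation(y_tr) if shuffle_training_labels else y_tr
        forest = ProximityForest(n_trees=n_trees, seed=seed, block_names=block_names)
        forest.fit(X_tr, y_fit)
        index = build_index(forest, X_tr, ids_tr, labels=y_tr)
        corpus_labels = dict(zip(ids_tr, y_tr))
        gvals = {k: [] for k in ks}
        X_te, y_te, _, _ = fuse(test, block_names)
        for row, label in zip(X_te, y_te):
            res = query(index, row, k=max(ks), with_uncertainty=False)
            for k in ks:
                p = precision_at_k(res, label, corpus_labels, k)
                per_query[k].append(p)
                gvals[k].append(p)
        per_group[g] = {k: float(np.mean(v)) for k, v in gvals.items()}

    return EvalReport(
        task=task,
        n_records=len(records),
        class_order=tuple(sorted({r.label for r in records})),
        precision_at_k={k: float(np.mean(v)) for k, v in per_query.items()},
        per_group=per_group,
        extras={
            "n_groups": len(groups),
            "null": bool(shuffle_training_labels),
            "seed": seed,
        },
    )


def permutation_null(records, task: str = "", seed: int = 0, **kwargs) -> EvalReport:
    """LOPO search with training labels shuffled: the chance level of
    precision@k under the identical pipeline."""
    return lopo_cv(records, task=task, seed=seed, shuffle_training_labels=True, **kwargs)


# ---------------------------------------------------------------------------
# rank-sum comparison of replicate sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    U: float  # statistic of the first sample
    U_complement: float  # n*m - U (the other sample's statistic)
    p: float
    method: str


def ranksum_compare(reps_a, reps_b, exact_limit: int = 12) -> RankSumResult:
    """Two-tailed Mann-Whitney rank-sum test between two replicate sets
    (midrank ties).  Exact enumeration when there are no ties and both
    samples have <= ``exact_limit`` values; otherwise the normal
    approximation with tie and continuity corrections."""
    a = np.asarray(reps_a, dtype=np.float64)
    b = np.asarray(reps_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per sample")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (not ties and len(a) <= exact_limit and len(b) <= exact_limit) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    U = float(res.statistic)
    return RankSumResult(U=U, U_complement=len(a) * len(b) - U, p=float(res.pvalue), method=method)
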