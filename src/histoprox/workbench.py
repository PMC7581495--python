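"""Manifest I/O, feature extraction and pipeline orchestration.

The unit of search and evaluation is a case: one image, its social-media
text, a contributor (pathologist) id, and optional gold labels.  Cases are
exchanged as JSONL manifests; features are assembled into named blocks and
fused for the forest.  ``run_pipeline`` wires the stages together with
content-hash caching so reruns are cheap and every artifact records the
seed and configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import joblib

from . import deepset, evalharness, handfeat, imgprep, proxforest, synthgen, textlabel

log = logging.getLogger("histoprox")


class ManifestError(ValueError):
    pass


@dataclass
class CaseRecord:
    """One case: image + text + contributor + optional gold labels."""

    id: str
    image_path: str
    text: textlabel.CaseText
    pathologist_id: str = ""
    gold: dict | None = None
    extra: dict = field(default_factory=dict)
    manifest_dir: Path | None = None

    def resolve_image(self) -> Path:
        base = self.manifest_dir or Path(".")
        return base / self.image_path


_KNOWN_FIELDS = {"id", "image_path", "text", "hashtags", "reply_texts", "pathologist_id", "gold"}


def load_manifest(path) -> list:
    """Parse a JSONL manifest into CaseRecords; duplicate ids are rejected
    and unknown fields preserved.  Image files are checked lazily at
    feature-extraction time."""
    path = Path(path)
    records = []
    seen = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                row = json.loads(line)
            except json.JSONDecodeError as e:
                raise ManifestError(f"{path}:{ln}: malformed JSON ({e})") from e
            for key in ("id", "image_path"):
                if key not in row:
                    raise ManifestError(f"{path}:{ln}: missing required field {key!r}")
            if row["id"] in seen:
                raise ManifestError(f"{path}:{ln}: duplicate id {row['id']!r}")
            seen.add(row["id"])
            records.append(
                CaseRecord(
                    id=row["id"],
                    image_path=row["image_path"],
                    text=textlabel.CaseText(
                        post_text=row.get("text", ""),
                        reply_texts=tuple(row.get("reply_texts", ())),
                        hashtags=tuple(row.get("hashtags", ())),
                    ),
                    pathologist_id=row.get("pathologist_id", ""),
                    gold=row.get("gold"),
                    extra={k: v for k, v in row.items() if k not in _KNOWN_FIELDS},
                    manifest_dir=path.parent,
                )
            )
    return records


def save_manifest(records, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in records:
            row = {
                "id": r.id,
                "image_path": r.image_path,
                "text": r.text.post_text,
                "hashtags": list(r.text.hashtags),
                "pathologist_id": r.pathologist_id,
                **({"gold": r.gold} if r.gold else {}),
                **({"reply_texts": list(r.text.reply_texts)} if r.text.reply_texts else {}),
                **r.extra,
            }
            fh.write(json.dumps(row) + "\n")
    return path


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def case_covariates(case: CaseRecord) -> textlabel.CovariateVector:
    """Clinical covariates parsed from the case text (weak supervision)."""
    labels = textlabel.parse_labels(case.text)
    return textlabel.encode_covariates(labels)


def extract_features(
    cases,
    blocks=("hand2412", "tissue10", "marker1"),
    sift_vocab=None,
    encoder=None,
    backbone=None,
    task: str = "disease3",
) -> list:
    """Compute the requested feature blocks for each case and fuse them into
    FusedRecords labeled by the task's gold label (cases without a task
    label are dropped)."""
    label_fn = evalharness.TASKS[task]
    needs_image = any(
        b in blocks for b in ("hand2412", "sift5", "deepset100", "generic2048")
    )
    missing = [c.id for c in cases if needs_image and not c.resolve_image().exists()]
    if missing:
        raise FileNotFoundError(f"image files missing for cases: {missing}")

    out = []
    for case in cases:
        gold = case.gold or {}
        label = label_fn(gold)
        if label is None:
            continue
        rec_blocks = {}
        std = None
        if needs_image:
            img = iio.imread(case.resolve_image())
            std = imgprep.standardize(img, source_id=case.id)
        if "hand2412" in blocks:
            rec_blocks["hand2412"] = handfeat.hand_engineered(std.crop512).values
        if "sift5" in blocks:
            if sift_vocab is None:
                raise ValueError("sift5 block requested but no vocabulary supplied")
            rec_blocks["sift5"] = handfeat.sift_bag(std.crop512, sift_vocab)
        if "deepset100" in blocks or "generic2048" in blocks:
            pset = imgprep.patch_grid(std)
            if "deepset100" in blocks:
                if encoder is None:
                    raise ValueError("deepset100 block requested but no encoder supplied")
                rec_blocks["deepset100"] = deepset.set_sum(encoder, pset).values
            if "generic2048" in blocks:
                rec_blocks["generic2048"] = deepset.pooled_generic(
                    backbone or deepset.StubBackbone(), pset
                ).values
        if "tissue10" in blocks or "marker1" in blocks:
            cov = case_covariates(case)
            forest_vec = cov.for_forest()
            if "tissue10" in blocks:
                rec_blocks["tissue10"] = forest_vec[:10]
            if "marker1" in blocks:
                rec_blocks["marker1"] = forest_vec[10:]
        out.append(
            proxforest.FusedRecord(
                blocks=rec_blocks,
                label=label,
                group_id=case.pathologist_id,
                record_id=case.id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# pipeline with content-hash caching
# ---------------------------------------------------------------------------

def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict) -> dict:
    """Run simulate -> extract -> train -> evaluate per the config.

    Config keys: ``seed``; ``data`` (either ``{"manifest": path}`` or
    ``{"simulate": {...SynthConfig fields...}, "out": dir}``); ``method``
    (a Fig-ladder name like ``method_i`` or an explicit
    ``{"blocks": [...], "n_members": n}``); ``task``; ``eval`` (``mode``
    in kfold/lopo/null plus parameters); ``n_trees``; ``cache_dir``;
    ``out_dir``.  Stage outputs are cached by content hash; artifacts embed
    the seed and config hash.
    """
    seed = int(config.get("seed", 0))
    cache_dir = Path(config.get("cache_dir", ".histoprox_cache"))
    out_dir = Path(config.get("out_dir", "histoprox_out"))
    cache_dir.mkdir(parents=True, exist_ok=True)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"config_hash": _config_hash(config), "seed": seed}

    # -- data -------------------------------------------------------------
    data_cfg = config.get("data", {})
    if "manifest" in data_cfg:
        manifest = Path(data_cfg["manifest"])
    else:
        sim = dict(data_cfg.get("simulate", {}))
        sim.setdefault("seed", seed)
        sim_dir = Path(data_cfg.get("out", out_dir / "synthetic"))
        key = _config_hash(sim)
        manifest = sim_dir / "manifest.jsonl"
        if not (manifest.exists() and (sim_dir / f".hash_{key}").exists()):
            manifest = synthgen.generate_dataset(synthgen.SynthConfig(**sim), sim_dir)
            (sim_dir / f".hash_{key}").touch()
            log.info("simulated dataset at %s (seed=%s)", sim_dir, sim.get("seed"))
    cases = load_manifest(manifest)
    artifacts["manifest"] = str(manifest)

    # -- method / features ------------------------------------------------
    method = config.get("method", "method_i")
    method_cfg = evalharness.METHODS[method] if isinstance(method, str) else dict(method)
    blocks = tuple(method_cfg["blocks"])
    n_members = int(method_cfg.get("n_members", 1))
    task = config.get("task", "disease3")
    n_trees = int(config.get("n_trees", 1000))

    def member_records(member_seed: int):
        sift_vocab = encoder = None
        if "sift5" in blocks:
            crops = []
            for case in cases:
                img = iio.imread(case.resolve_image())
                crops.append(imgprep.standardize(img).crop512)
            sift_vocab = handfeat.fit_sift_vocabulary(crops, k=5, seed=member_seed)
        if "deepset100" in blocks:
            encoder = _fit_encoder(cases, task, member_seed)
        return extract_features(
            cases, blocks, sift_vocab=sift_vocab, encoder=encoder,
            backbone=deepset.StubBackbone(seed=member_seed), task=task,
        )

    feat_key = _config_hash(
        {"manifest": synthgen.manifest_hash(manifest), "blocks": blocks,
         "task": task, "seed": seed, "n_members": n_members}
    )
    feat_path = cache_dir / f"features_{feat_key}.joblib"
    if feat_path.exists():
        member_recs = joblib.load(feat_path)
        log.info("feature cache hit: %s", feat_path)
    else:
        member_recs = [member_records(seed + m) for m in range(n_members)]
        joblib.dump(member_recs, feat_path)
    artifacts["features"] = str(feat_path)

    # -- train ------------------------------------------------------------
    members = []
    for m, recs in enumerate(member_recs):
        forest = proxforest.train_forest(recs, n_trees=n_trees, seed=seed + m, block_names=blocks)
        members.append(forest)
    model = proxforest.EnsembleModel(members=members) if n_members > 1 else members[0]
    model_path = out_dir / f"model_{method if isinstance(method, str) else 'custom'}_{feat_key}.joblib"
    joblib.dump({"model": model, "seed": seed, "config_hash": artifacts["config_hash"]}, model_path)
    artifacts["model"] = str(model_path)

    # -- evaluate ---------------------------------------------------------
    eval_cfg = dict(config.get("eval", {}))
    mode = eval_cfg.pop("mode", None)
    if mode:
        records = member_recs[0]
        report_key = _config_hash({"feat": feat_key, "eval": {**eval_cfg, "mode": mode}, "n_trees": n_trees})
        report_path = out_dir / f"report_{report_key}.json"
        if report_path.exists():
            report = json.loads(report_path.read_text())
            log.info("report cache hit: %s", report_path)
        else:
            if mode == "kfold":
                rep = evalharness.kfold_replicates(
                    records, task=task, n_trees=n_trees, block_names=blocks, **eval_cfg
                )
            elif mode == "lopo":
                rep = evalharness.lopo_cv(
                    records, task=task, n_trees=n_trees, seed=seed, block_names=blocks, **eval_cfg
                )
            elif mode == "null":
                rep = evalharness.permutation_null(
                    records, task=task, seed=seed, n_trees=n_trees, block_names=blocks, **eval_cfg
                )
            else:
                raise ValueError(f"unknown eval mode {mode!r}")
            report = json.loads(rep.to_json())
            report["seed"] = seed
            report["config_hash"] = artifacts["config_hash"]
            report_path.write_text(json.dumps(report, indent=2))
        artifacts["report"] = str(report_path)
        artifacts["report_data"] = report
    return artifacts


def _fit_encoder(cases, task: str, seed: int):
    """Train a patch encoder on center patches of the cases (weak patch
    labels inherited from the image label)."""
    label_fn = evalharness.TASKS[task]
    patches, labels, covs = [], [], []
    for case in cases:
        gold = case.gold or {}
        label = label_fn(gold)
        if label is None:
            continue
        img = iio.imread(case.resolve_image())
        std = imgprep.standardize(img)
        c0 = (512 - imgprep.PATCH) // 2
        patches.append(std.crop512[c0 : c0 + imgprep.PATCH, c0 : c0 + imgprep.PATCH])
        labels.append(label)
        covs.append(case_covariates(case).for_network())
    cfg = deepset.EncoderConfig(seed=seed, epochs=5)
    return deepset.train_encoder(patches, labels, covs, cfg)
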