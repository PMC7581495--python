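"""Patch encoder, 100-d approximately-binary head and set representation.

An image is represented order-invariantly by summing per-patch encoder
outputs over the fixed 21-patch grid.  The encoder is pluggable:

* a deterministic stub backbone (seeded random projection of patch
  statistics) that satisfies every interface contract without training, and
* a small trainable network: a fixed convolutional-statistics descriptor
  feeding a hidden layer and a 100-unit head squashed by a steep sigmoid
  ``sigmoid(tau * z)`` with a binarization penalty ``lam * mean(x (1 - x))``
  that pushes head outputs toward {0, 1}, plus a softmax disease-state head
  over the head outputs concatenated with the clinical covariates.

A heavier convolutional backbone (e.g. an ImageNet-pretrained network) can
be plugged in through the same ``backbone`` callable contract; nothing
downstream depends on more than the output dimension.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .imgprep import AugmentConfig, N_PATCHES, PATCH, PatchSet, augment

HEAD_DIM = 100
GENERIC_DIM = 2048
COVARIATE_DIM = 11  # 10 tissue one-hot + marker bit
_DESC_DIM = 28 * 28 + 6


@dataclass(frozen=True)
class DeepSetVector:
    """Sum of the 21 per-patch 100-d head outputs; entries in [0, 21]."""

    values: np.ndarray
    n_patches: int = N_PATCHES

    def __post_init__(self) -> None:
        if self.values.shape != (HEAD_DIM,):
            raise ValueError(f"expected {HEAD_DIM} values")


@dataclass(frozen=True)
class PooledGenericFeatures:
    """Sum over the 21 patches of a generic 2048-d pooled backbone output."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (GENERIC_DIM,):
            raise ValueError(f"expected {GENERIC_DIM} values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values")


def patch_descriptor(patch: np.ndarray) -> np.ndarray:
    """Fixed descriptor of a 224x224x3 patch: 28x28 gray block means plus
    per-channel mean/std, all on a 0..1 scale.  Maps the zero image to the
    zero vector."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (PATCH, PATCH, 3):
        raise ValueError(f"patch must be {PATCH}x{PATCH}x3")
    gray = patch.mean(axis=2) / 255.0
    blocks = gray.reshape(28, 8, 28, 8).mean(axis=(1, 3)).ravel()
    chan = patch.reshape(-1, 3) / 255.0
    stats = np.concatenate([chan.mean(axis=0), chan.std(axis=0)])
    return np.concatenate([blocks, stats])


class StubBackbone:
    """Deterministic zero-centered backbone: seeded linear projection of the
    patch descriptor through tanh.  Fills in for a pretrained convolutional
    network in tests and offline runs."""

    def __init__(self, dim: int = GENERIC_DIM, seed: int = 0) -> None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2048]))
        self.dim = dim
        self.seed = seed
        self._w = rng.normal(0, 1.0 / np.sqrt(_DESC_DIM), (_DESC_DIM, dim))

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        return np.tanh(patch_descriptor(patch) @ self._w)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass
class EncoderConfig:
    hidden: int = 64
    tau: float = 4.0  # steep-sigmoid slope for approximately-binary outputs
    binarization_weight: float = 0.01  # lam in lam * mean(x (1 - x))
    epochs: int = 10
    lr: float = 3e-3
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    use_mixup: bool = True


class PatchEncoder:
    """Patch -> 100-d approximately-binary features plus a 3-way class head.

    ``class_activations`` are softmax outputs: non-negative, summing to 1
    per patch.  Untrained encoders (seeded random weights) already satisfy
    every interface contract and serve as the deterministic stub.
    """

    def __init__(
        self,
        class_order,
        config: EncoderConfig | None = None,
        backbone=None,
    ) -> None:
        self.config = config or EncoderConfig()
        self.class_order = tuple(class_order)
        self.backbone = backbone  # optional generic 2048-d feature map
        self.training_meta: dict = {"seed": self.config.seed, "trained": False}
        rng = np.random.default_rng(np.random.SeedSequence([self.config.seed, 77]))
        h = self.config.hidden
        self._params = {
            "w1": rng.normal(0, np.sqrt(2.0 / _DESC_DIM), (_DESC_DIM, h)),
            "b1": np.zeros(h),
            "w2": rng.normal(0, np.sqrt(1.0 / h), (h, HEAD_DIM)),
            "b2": np.zeros(HEAD_DIM),
            "w3": rng.normal(
                0, np.sqrt(1.0 / (HEAD_DIM + COVARIATE_DIM)),
                (HEAD_DIM + COVARIATE_DIM, len(self.class_order)),
            ),
            "b3": np.zeros(len(self.class_order)),
        }

    # -- forward ----------------------------------------------------------
    def _forward(self, desc: np.ndarray, cov: np.ndarray):
        p = self._params
        a1 = desc @ p["w1"] + p["b1"]
        h1 = np.maximum(a1, 0.0)
        z = h1 @ p["w2"] + p["b2"]
        head = _sigmoid(self.config.tau * z)
        inp = np.concatenate([head, cov])
        logits = inp @ p["w3"] + p["b3"]
        return a1, h1, z, head, inp, logits

    def encode(self, patch: np.ndarray) -> np.ndarray:
        desc = patch_descriptor(patch)
        return self._forward(desc, np.zeros(COVARIATE_DIM))[3]

    def class_activations(self, patch: np.ndarray, covariates=None) -> np.ndarray:
        cov = np.zeros(COVARIATE_DIM) if covariates is None else np.asarray(covariates, float)
        desc = patch_descriptor(patch)
        return _softmax(self._forward(desc, cov)[5])

    def weights_hash(self) -> str:
        blob = b"".join(self._params[k].tobytes() for k in sorted(self._params))
        return hashlib.sha256(blob).hexdigest()


def encode_patch(enc: PatchEncoder, patch: np.ndarray) -> np.ndarray:
    """100 head outputs in [0, 1] for one 224x224x3 patch."""
    return enc.encode(patch)


def set_sum(enc: PatchEncoder, patchset: PatchSet) -> DeepSetVector:
    """Order-independent elementwise sum of the 21 per-patch head outputs."""
    if len(patchset.patches) != N_PATCHES:
        raise ValueError(f"expected exactly {N_PATCHES} patches")
    total = np.zeros(HEAD_DIM)
    for patch in patchset.patches:
        total += enc.encode(patch)
    return DeepSetVector(values=total)


def pooled_generic(backbone, patchset: PatchSet) -> PooledGenericFeatures:
    """Sum of the backbone's 2048-d pooled output over the 21 patches."""
    if backbone is None:
        raise ValueError(
            "no backbone configured; supply a pretrained plug-in or StubBackbone"
        )
    total = np.zeros(GENERIC_DIM)
    for patch in patchset.patches:
        total += backbone(patch)
    return PooledGenericFeatures(values=total)


def train_encoder(
    patches,
    labels,
    covariates=None,
    config: EncoderConfig | None = None,
) -> PatchEncoder:
    """Train the patch encoder on patch-level disease-state labels.

    Patches inherit their image's label (weak labeling).  Each epoch applies
    the standard augmentation chain, including Mixup target mixing; the loss
    is cross-entropy plus the binarization penalty.  Fully deterministic
    given the config seed (single-threaded NumPy SGD with Adam updates).
    """
    cfg = config or EncoderConfig()
    labels = list(labels)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train the encoder")
    patches = [np.asarray(p) for p in patches]
    n = len(patches)
    if covariates is None:
        covariates = [np.zeros(COVARIATE_DIM)] * n
    covariates = [np.asarray(c, dtype=np.float64) for c in covariates]
    y_idx = np.array([classes.index(l) for l in labels])

    enc = PatchEncoder(class_order=classes, config=cfg)
    p = enc._params
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    adam_m = {k: np.zeros_like(v) for k, v in p.items()}
    adam_v = {k: np.zeros_like(v) for k, v in p.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    k = len(classes)
    loss_trace = []

    def epoch_loss() -> float:
        tot = 0.0
        for i in range(n):
            desc = patch_descriptor(patches[i])
            *_, head, _, logits = enc._forward(desc, covariates[i])
            probs = _softmax(logits)
            tot += -np.log(probs[y_idx[i]] + 1e-12)
            tot += cfg.binarization_weight * float(np.mean(head * (1 - head)))
        return tot / n

    loss_trace.append(epoch_loss())  # epoch-0 (pre-training) loss

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for i in order:
            target = np.zeros(k)
            target[y_idx[i]] = 1.0
            if cfg.use_mixup and cfg.augment.mixup_alpha > 0:
                j = int(rng.integers(n))
                patch_aug, lam = augment(
                    patches[i], rng, cfg.augment, mix_with=patches[j]
                )
                partner = np.zeros(k)
                partner[y_idx[j]] = 1.0
                target = lam * target + (1 - lam) * partner
            else:
                patch_aug, _ = augment(patches[i], rng, cfg.augment)
            desc = patch_descriptor(patch_aug)
            cov = covariates[i]

            a1, h1, z, head, inp, logits = enc._forward(desc, cov)
            probs = _softmax(logits)

            # gradients: softmax CE wrt logits, then chain through the head
            d_logits = probs - target
            g = {
                "w3": np.outer(inp, d_logits),
                "b3": d_logits,
            }
            d_inp = p["w3"] @ d_logits
            d_head = d_inp[:HEAD_DIM]
            d_head = d_head + cfg.binarization_weight * (1 - 2 * head) / HEAD_DIM
            d_z = d_head * cfg.tau * head * (1 - head)
            g["w2"] = np.outer(h1, d_z)
            g["b2"] = d_z
            d_h1 = p["w2"] @ d_z
            d_a1 = d_h1 * (a1 > 0)
            g["w1"] = np.outer(desc, d_a1)
            g["b1"] = d_a1

            step += 1
            for key in p:
                adam_m[key] = beta1 * adam_m[key] + (1 - beta1) * g[key]
                adam_v[key] = beta2 * adam_v[key] + (1 - beta2) * g[key] ** 2
                mh = adam_m[key] / (1 - beta1**step)
                vh = adam_v[key] / (1 - beta2**step)
                p[key] -= cfg.lr * mh / (np.sqrt(vh) + eps)
        loss_trace.append(epoch_loss())

    enc.training_meta = {
        "seed": cfg.seed,
        "epochs": cfg.epochs,
        "trained": True,
        "loss_trace": loss_trace,
        "classes": classes,
    }
    return enc


def binarization_gap(enc: PatchEncoder, patches) -> float:
    """mean(min(x, 1 - x)) of head outputs over the given patches; small
    values mean the head is close to binary."""
    vals = [np.minimum(h := enc.encode(p), 1 - h).mean() for p in patches]
    return float(np.mean(vals))


def select_deep3(importances) -> np.ndarray:
    """Indices of the 3 largest importances, ties broken by lower index."""
    imp = np.asarray(importances, dtype=np.float64)
    if imp.ndim != 1 or len(imp) < 3:
        raise ValueError("need an importance vector of length >= 3")
    return np.argsort(-imp, kind="stable")[:3]
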