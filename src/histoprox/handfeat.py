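"""Task-agnostic hand-engineered image features (2412 dims) and the
bag-of-SIFT-clusters block.

The 2412-dimensional vector concatenates, in the fixed order of
:data:`BLOCK_TABLE`: per-channel RGB and HSV histograms, a gray histogram, a
Local Binary Patterns Pyramid (three (P, R) configurations over a 6-level
half-resolution pyramid), Sobel orientation histograms per pyramid level,
13 Haralick co-occurrence statistics at 4 offsets, the 7 Hu moment
invariants and per-channel mean/std/entropy summary statistics.  Histogram
blocks are individually L1-normalized so each sums to 1 whenever the
underlying pixels (or gradient pixels) exist.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.feature import SIFT, graycomatrix, local_binary_pattern
from skimage.measure import moments_central, moments_hu, moments_normalized
from skimage.transform import pyramid_gaussian
from sklearn.cluster import KMeans

N_FEATURES = 2412
PYRAMID_LEVELS = 6
LBP_CONFIGS = ((8, 1), (16, 2), (24, 3))  # riu2 -> P + 2 bins each
ORIENT_BINS = 36
GLCM_LEVELS = 64
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
N_HARALICK = 13


def _build_block_table() -> dict:
    table = {}
    pos = 0

    def add(name: str, length: int) -> None:
        nonlocal pos
        table[name] = slice(pos, pos + length)
        pos += length

    for ch in "rgb":
        add(f"rgb_hist_{ch}", 256)
    for ch in "hsv":
        add(f"hsv_hist_{ch}", 256)
    add("gray_hist", 256)
    for level in range(PYRAMID_LEVELS):
        for p, r in LBP_CONFIGS:
            add(f"lbpp_l{level}_p{p}r{r}", p + 2)
    for level in range(PYRAMID_LEVELS):
        add(f"sobel_orient_l{level}", ORIENT_BINS)
    add("glcm_haralick", N_HARALICK * len(GLCM_ANGLES))
    add("hu_moments", 7)
    add("channel_stats", 21)
    assert pos == N_FEATURES, f"block table sums to {pos}, expected {N_FEATURES}"
    return table


#: name -> slice into the 2412-vector; validated at import time.
BLOCK_TABLE = _build_block_table()


@dataclass(frozen=True)
class HandFeatures:
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    def block(self, name: str) -> np.ndarray:
        return self.values[BLOCK_TABLE[name]]


def _norm_hist(hist: np.ndarray) -> np.ndarray:
    total = hist.sum()
    return hist / total if total > 0 else hist.astype(np.float64)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def _haralick(glcm: np.ndarray) -> np.ndarray:
    """13 Haralick statistics from one normalized co-occurrence matrix."""
    n = glcm.shape[0]
    idx = np.arange(n, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    p = glcm
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sd_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 0..2n-2 and p_{x-y}(k), k = 0..n-1
    ksum = (i + j).astype(int)
    kdiff = np.abs(i - j).astype(int)
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * n - 1)
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=n)
    k_s = np.arange(2 * n - 1, dtype=np.float64)
    k_d = idx

    asm = float((p**2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    corr = (
        float(((i * j * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
        if sd_x > 0 and sd_y > 0
        else 0.0
    )
    variance = float(((i - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    sum_avg = float((k_s * p_sum).sum())
    sum_var = float(((k_s - sum_avg) ** 2 * p_sum).sum())
    sum_ent = _entropy(p_sum) * np.log(2)  # natural-log convention
    entropy = _entropy(p.ravel()) * np.log(2)
    diff_avg = float((k_d * p_diff).sum())
    diff_var = float(((k_d - diff_avg) ** 2 * p_diff).sum())
    diff_ent = _entropy(p_diff) * np.log(2)

    with np.errstate(divide="ignore", invalid="ignore"):
        hx = _entropy(px) * np.log(2)
        hy = _entropy(py) * np.log(2)
        pxy = px[:, None] * py[None, :]
        mask = (p > 0) & (pxy > 0)
        hxy1 = float(-(p[mask] * np.log(pxy[mask])).sum())
        mask2 = pxy > 0
        hxy2 = float(-(pxy[mask2] * np.log(pxy[mask2])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array(
        [asm, contrast, corr, variance, idm, sum_avg, sum_var, sum_ent,
         entropy, diff_var, diff_ent, imc1, imc2],
    )


def hand_engineered(crop: np.ndarray) -> HandFeatures:
    """Compute the 2412 hand-engineered features of a 512x512x3 crop.

    Purely pixel-determined: identical crops yield identical vectors.
    """
    crop = np.asarray(crop)
    if crop.shape != (512, 512, 3):
        raise ValueError("crop must be exactly 512x512x3")
    crop = crop.astype(np.uint8)
    out = np.zeros(N_FEATURES, dtype=np.float64)

    hsv = rgb2hsv(crop)  # floats in [0, 1]
    gray = rgb2gray(crop)  # float in [0, 1]
    gray8 = np.clip(np.rint(gray * 255), 0, 255).astype(np.uint8)

    for c, ch in enumerate("rgb"):
        hist = np.bincount(crop[:, :, c].ravel(), minlength=256)[:256]
        out[BLOCK_TABLE[f"rgb_hist_{ch}"]] = _norm_hist(hist)
    for c, ch in enumerate("hsv"):
        hist, _ = np.histogram(hsv[:, :, c], bins=256, range=(0.0, 1.0))
        out[BLOCK_TABLE[f"hsv_hist_{ch}"]] = _norm_hist(hist)
    out[BLOCK_TABLE["gray_hist"]] = _norm_hist(
        np.bincount(gray8.ravel(), minlength=256)[:256]
    )

    # texture/edge pyramid: half-resolution levels 512 .. 16
    levels = [
        lvl
        for _, lvl in zip(
            range(PYRAMID_LEVELS),
            pyramid_gaussian(gray, max_layer=PYRAMID_LEVELS - 1, downscale=2),
        )
    ]
    for level, img in enumerate(levels):
        img8 = np.rint(img * 255).astype(np.int32)  # exact monotone-shift behavior
        for p, r in LBP_CONFIGS:
            codes = local_binary_pattern(img8, p, r, method="uniform")
            hist = np.bincount(codes.astype(int).ravel(), minlength=p + 2)[: p + 2]
            out[BLOCK_TABLE[f"lbpp_l{level}_p{p}r{r}"]] = _norm_hist(hist)
        gy, gx = np.gradient(img)
        mag = np.hypot(gx, gy)
        orient = np.arctan2(gy, gx)  # [-pi, pi]
        hist, _ = np.histogram(
            orient, bins=ORIENT_BINS, range=(-np.pi, np.pi), weights=mag
        )
        out[BLOCK_TABLE[f"sobel_orient_l{level}"]] = _norm_hist(hist)

    quant = (gray8.astype(np.int32) * GLCM_LEVELS // 256).astype(np.uint8)
    glcm = graycomatrix(
        quant, distances=[1], angles=list(GLCM_ANGLES), levels=GLCM_LEVELS,
        symmetric=True, normed=True,
    )
    har = np.concatenate(
        [_haralick(glcm[:, :, 0, a]) for a in range(len(GLCM_ANGLES))]
    )
    out[BLOCK_TABLE["glcm_haralick"]] = har

    mu = moments_central(gray)
    nu = moments_normalized(mu)
    hu = moments_hu(nu)
    # signed-log scale keeps the 7 invariants in a comparable numeric range
    out[BLOCK_TABLE["hu_moments"]] = -np.sign(hu) * np.log10(np.abs(hu) + 1e-30)

    channels = [crop[:, :, c].astype(np.float64) / 255.0 for c in range(3)]
    channels += [hsv[:, :, c] for c in range(3)]
    channels.append(gray)
    stats = []
    for ch in channels:
        hist, _ = np.histogram(ch, bins=256, range=(0.0, 1.0))
        stats += [float(ch.mean()), float(ch.std()), _entropy(_norm_hist(hist))]
    out[BLOCK_TABLE["channel_stats"]] = stats

    return HandFeatures(values=out)


# ---------------------------------------------------------------------------
# bag of SIFT clusters ("most prevalent first")
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiftVocabulary:
    """k centroids of 128-d SIFT descriptors, ordered most-prevalent first.

    Fitted on training-fold descriptors only to keep held-out groups clean.
    """

    centroids: np.ndarray  # (k, 128)
    counts: np.ndarray  # descriptors assigned per centroid at fit time
    seed: int
    training_hash: str

    @property
    def k(self) -> int:
        return len(self.centroids)


def sift_descriptors(crop: np.ndarray) -> np.ndarray:
    """Difference-of-Gaussian SIFT descriptors of a crop's gray image;
    shape (n, 128), possibly empty."""
    gray = rgb2gray(np.asarray(crop))
    det = SIFT()
    try:
        det.detect_and_extract(gray)
    except RuntimeError:  # no keypoints found
        return np.empty((0, 128), dtype=np.float64)
    if det.descriptors is None or len(det.descriptors) == 0:
        return np.empty((0, 128), dtype=np.float64)
    return det.descriptors.astype(np.float64)


def fit_sift_vocabulary(crops, k: int = 5, seed: int = 0) -> SiftVocabulary:
    """Pool SIFT descriptors over training crops and k-means them into k
    clusters, centroids ordered by descending assigned-descriptor count."""
    desc = [sift_descriptors(c) for c in crops]
    pooled = np.vstack([d for d in desc if len(d)]) if any(len(d) for d in desc) else np.empty((0, 128))
    if len(pooled) < k:
        raise ValueError(
            f"only {len(pooled)} SIFT descriptors found; need >= {k}. "
            "Provide a larger or more textured training set."
        )
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(pooled)
    counts = np.bincount(km.labels_, minlength=k)
    order = np.argsort(-counts, kind="stable")
    h = hashlib.sha256(pooled.tobytes()).hexdigest()[:16]
    return SiftVocabulary(
        centroids=km.cluster_centers_[order],
        counts=counts[order],
        seed=seed,
        training_hash=h,
    )


def sift_bag(crop: np.ndarray, vocab: SiftVocabulary) -> np.ndarray:
    """L1-normalized histogram of descriptor-to-nearest-centroid assignments;
    the zero vector when the crop has no keypoints."""
    desc = sift_descriptors(crop)
    if len(desc) == 0:
        return np.zeros(vocab.k)
    d2 = ((desc[:, None, :] - vocab.centroids[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    hist = np.bincount(assign, minlength=vocab.k).astype(np.float64)
    return hist / hist.sum()
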