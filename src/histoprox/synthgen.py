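"""Synthetic photomicrograph corpus generator.

Emulates the statistical structure of a social-media pathology corpus so the
whole pipeline is testable without any real data: three disease states
separable mainly by nuclear texture (blob density / size / pleomorphism),
ten tissue-type color contexts, stain palettes (H&E-like pink/purple,
IHC-like brown, other/gray), per-pathologist tint and exposure artifacts,
and hashtag/keyword text that the weak-supervision parser maps back onto the
generating labels.

Class signal is carried by texture statistics rather than color, so tissue
tint and pathologist tint act as confounders — with artifact strength high
and the class signal removed, a classifier can learn the contributor rather
than the disease, which is exactly the leakage mode that
leave-one-pathologist-out evaluation is designed to expose.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import ellipse

from .textlabel import DISEASES, MISSING, STAINS, TISSUES, CaseText

IMG_SIZE = 512

# stain palettes: (background RGB, nucleus RGB)
STAIN_PALETTES = {
    "HE": ((236, 208, 228), (92, 58, 132)),
    "IHC": ((228, 216, 198), (122, 78, 40)),
    "other": ((212, 212, 212), (82, 82, 82)),
}

# small deterministic per-tissue background tints (RGB offsets)
_TISSUE_TINTS = np.array(
    [
        [6, 0, -6], [-8, 4, 0], [0, -6, 6], [8, 8, 0], [-6, -6, 6],
        [0, 8, -8], [-8, 0, 8], [6, -8, 0], [0, 0, 10], [-10, 6, -4],
    ],
    dtype=np.float64,
)


@dataclass
class ClassTexture:
    """Nuclear texture statistics of one disease state.

    Blob radii are lognormal (``radius_sd`` is the log-scale spread, i.e.
    relative size pleomorphism); eccentricity is area-preserving, so the
    chromatin area fraction depends only on density * E[r^2]."""

    density: float  # mean blob count per image
    radius_mean: float  # px, median radius
    radius_sd: float  # lognormal sigma (relative spread)
    ecc_sd: float  # log axis-ratio spread (shape pleomorphism)
    tone_sd: float = 0.05  # per-blob stain-darkness spread (hyperchromasia)
    cluster_frac: float = 0.0  # fraction of blobs crowding around foci


@dataclass
class SynthConfig:
    n_images: int = 300
    n_pathologists: int = 10
    class_mix: tuple = (1 / 3, 1 / 3, 1 / 3)  # nontumor, low_grade, malignant
    tissue_mix: tuple = tuple([0.1] * 10)
    stain_mix: tuple = (0.6, 0.3, 0.1)  # HE, IHC, other
    # Class signal is pleomorphism (within-image dispersion of nuclear size
    # and shape), not pixel mass: density * radius_mean^2 * exp(2 radius_sd^2)
    # is matched across classes (~8200 px^2 per 100 blobs) so every class
    # stamps the same chromatin area, and the scale/count marginals are
    # washed by the magnification spread.  Supervised trees must find the
    # dispersion features; a label-shuffled forest groups cases by
    # stain/exposure instead of disease.
    textures: dict = field(
        default_factory=lambda: {
            "nontumor": ClassTexture(100, 9.03, 0.05, 0.05, 0.03, 0.0),
            "low_grade": ClassTexture(225, 5.58, 0.28, 0.28, 0.03, 0.0),
            "malignant": ClassTexture(400, 3.34, 0.55, 0.55, 0.03, 0.0),
        }
    )
    exposure_jitter: float = 0.05  # per-image camera gain/offset spread
    # Photomicrographs come at uncontrolled magnification: a per-image
    # lognormal zoom scales blob size up and count down (field of view),
    # leaving the chromatin area fraction invariant.
    magnification_jitter: float = 0.58
    focus_blur_max: float = 1.5  # per-image defocus, Gaussian sigma in px
    artifact_strength: float = 0.08  # per-pathologist tint/gain jitter
    # marker tests (IHC etc.) are discussed mostly when malignancy is
    # suspected, so the mention rate depends on the disease state
    # (~25% of cases overall)
    marker_rate: dict = field(
        default_factory=lambda: {"nontumor": 0.08, "low_grade": 0.22, "malignant": 0.50}
    )
    tissue_missing_rate: float = 0.1  # cases whose text omits the tissue
    text_noise_rate: float = 0.05
    pathologist_weights: tuple | None = None  # None -> equal round-robin
    # Disease mix varies by tissue (as in real corpora: some tissues are
    # shared mostly for low-grade lesions, others mostly for malignancies):
    # tissue j < 9 favors class j mod 3 by +skew (others -skew/2), tissue 9
    # is balanced, so the global class mix stays exactly class_mix.
    tissue_class_skew: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix, k in (
            ("class_mix", self.class_mix, 3),
            ("tissue_mix", self.tissue_mix, 10),
            ("stain_mix", self.stain_mix, 3),
        ):
            if len(mix) != k or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must have {k} proportions summing to 1")
        if self.n_images < 1 or self.n_pathologists < 1:
            raise ValueError("counts must be >= 1")


def pathologist_artifact(index: int, strength: float, seed: int = 0):
    """Fixed per-pathologist channel gains and brightness offset."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919, index]))
    gains = 1.0 + strength * rng.normal(0, 1, 3)
    offset = strength * 60.0 * rng.normal()
    return gains, offset


def sample_blobs(
    tex: ClassTexture,
    rng: np.random.Generator,
    magnification: float = 1.0,
    area_jitter: float = 0.25,
):
    """Blob parameter list (center, axes, rotation, tone) for one image.

    Blobs are drawn until a per-image chromatin *area budget* is filled.
    The budget, ``density * pi * radius_mean^2 * exp(2 radius_sd^2)`` times
    a shared lognormal jitter, is identical across the default classes, so
    the realized chromatin area fraction is class-independent both in mean
    and in spread — only the way the area is split into nuclei (count,
    size/shape dispersion) differs, which is the intended texture signal.
    """
    expected_area = tex.density * np.pi * tex.radius_mean**2 * np.exp(2 * tex.radius_sd**2)
    budget = expected_area * float(np.exp(rng.normal(0, area_jitter)))
    max_count = int(4 * tex.density / magnification**2) + 8
    foci = rng.uniform(0, IMG_SIZE, (5, 2))  # crowding foci
    blobs = []
    filled = 0.0
    while filled < budget and len(blobs) < max_count:
        rb = magnification * tex.radius_mean * float(np.exp(rng.normal(0, tex.radius_sd)))
        rb = max(1.5, rb)
        # area-preserving eccentricity: axes rb*e^(eps/2), rb*e^(-eps/2)
        eps = rng.normal(0, tex.ecc_sd)
        r1 = rb * float(np.exp(abs(eps) / 2))
        r2 = rb * float(np.exp(-abs(eps) / 2))
        if rng.random() < tex.cluster_frac:
            focus = foci[rng.integers(0, len(foci))]
            cr, cc = focus + rng.normal(0, 30.0 * magnification, 2)
        else:
            cr, cc = rng.uniform(0, IMG_SIZE, 2)
        # mean-one lognormal tone: dispersion without a mean-darkness shift
        tone = float(np.exp(rng.normal(-tex.tone_sd**2 / 2, tex.tone_sd)))
        blobs.append((cr, cc, r1, r2, rng.uniform(0, np.pi), tone))
        filled += np.pi * r1 * r2
    return blobs


def render_image(
    disease: str,
    tissue: str,
    stain: str,
    artifact,
    rng: np.random.Generator,
    cfg: SynthConfig | None = None,
) -> np.ndarray:
    """Render one 512x512 RGB photomicrograph-like raster."""
    cfg = cfg or SynthConfig()
    bg, nucleus = STAIN_PALETTES[stain]
    canvas = np.empty((IMG_SIZE, IMG_SIZE, 3), dtype=np.float64)
    canvas[:] = np.asarray(bg, dtype=np.float64)
    canvas += _TISSUE_TINTS[TISSUES.index(tissue)]
    # per-image slide/section nuisance: structured stromal texture at a
    # random correlation length (collagen/cytoplasm grain), stain depth
    from scipy.ndimage import gaussian_filter

    stroma_amp = rng.uniform(3.0, 10.0)
    stroma_len = rng.uniform(0.5, 16.0)
    field = gaussian_filter(rng.normal(0, 1, (IMG_SIZE, IMG_SIZE)), stroma_len)
    sd = field.std()
    if sd > 0:
        canvas += (stroma_amp / sd) * field[:, :, None]
    stain_depth = rng.uniform(0.65, 0.95)
    nucleus_tone = rng.uniform(0.8, 1.2)

    # collagen-like fiber strands: gently curved dark/light streaks whose
    # per-image density varies widely; they dominate gradient-orientation
    # and fine-texture statistics independently of any label
    n_fibers = int(rng.poisson(rng.uniform(0.0, 25.0)))
    for _ in range(n_fibers):
        x0, y0 = rng.uniform(0, IMG_SIZE, 2)
        theta = rng.uniform(0, np.pi)
        length = rng.uniform(60, 400)
        curve = rng.normal(0, 0.002)
        thickness = rng.integers(1, 4)
        shade = rng.uniform(-55, 35)
        t = np.arange(0, length)
        xs = (x0 + t * np.cos(theta) + curve * t**2).astype(int)
        ys = (y0 + t * np.sin(theta)).astype(int)
        ok = (xs >= 0) & (xs < IMG_SIZE) & (ys >= 0) & (ys < IMG_SIZE)
        for dr in range(int(thickness)):
            xr = np.clip(xs[ok] + dr, 0, IMG_SIZE - 1)
            canvas[xr, ys[ok]] += shade

    nucleus = np.asarray(nucleus, dtype=np.float64) * nucleus_tone
    magnification = float(np.exp(rng.normal(0, cfg.magnification_jitter)))
    for cr, cc, r1, r2, rot, tone in sample_blobs(cfg.textures[disease], rng, magnification):
        rr, cc_ = ellipse(cr, cc, r1, r2, shape=(IMG_SIZE, IMG_SIZE), rotation=rot)
        color = nucleus * tone * (1.0 + 0.1 * rng.normal(0, 1, 3))
        canvas[rr, cc_] = (1 - stain_depth) * canvas[rr, cc_] + stain_depth * color

    if cfg.focus_blur_max > 0:  # variable focus quality
        from scipy.ndimage import gaussian_filter

        sigma = rng.uniform(0.0, cfg.focus_blur_max)
        canvas = gaussian_filter(canvas, sigma=(sigma, sigma, 0))

    gains, offset = artifact
    canvas = canvas * np.asarray(gains) + offset
    # per-image exposure/tint jitter, independent of every label
    canvas = canvas * (1.0 + cfg.exposure_jitter * rng.normal(0, 1, 3))
    canvas += cfg.exposure_jitter * 100.0 * rng.normal()
    canvas += rng.normal(0, 2.0, canvas.shape)  # camera noise
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8)


_TISSUE_TAGS = {
    "bone_soft_tissue": "bstpath",
    "breast": "breastpath",
    "dermatological": "dermpath",
    "gastrointestinal": "gipath",
    "genitourinary": "gupath",
    "gynecological": "gynpath",
    "head_neck": "headneckpath",
    "hematological": "hemepath",
    "neurological": "neuropath",
    "pulmonary": "pulmpath",
}
_DISEASE_WORDS = {
    "nontumor": ("normal", "inflammation", "granulation tissue", "infection"),
    "low_grade": ("benign", "carcinoma in situ", "hyperplasia", "adenoma"),
    "malignant": ("carcinoma", "adenocarcinoma", "sarcoma", "metastatic"),
}
_STAIN_TAGS = {"HE": "he", "IHC": "ihc", "other": "pas"}
_MARKER_WORDS = ("desmin", "ki67", "her2", "cd34", "p53")


def generate_text(labels, rng: np.random.Generator, noise_rate: float = 0.0) -> CaseText:
    """Hashtag/keyword text that the default rule tables parse back to the
    given labels with probability 1 - noise_rate; corrupted (unparseable)
    otherwise.  ``labels`` needs fields tissue, disease, stain,
    marker_mention; tissue may be MISSING to omit the tissue hashtag."""
    if rng.random() < noise_rate:
        return CaseText(post_text="interesting case for discussion", hashtags=())
    words = [str(rng.choice(_DISEASE_WORDS[labels.disease]))]
    tags = []
    if labels.tissue != MISSING:
        tags.append(_TISSUE_TAGS[labels.tissue])
    if labels.stain != MISSING:
        tags.append(_STAIN_TAGS[labels.stain])
    if labels.marker_mention:
        words.append(f"{rng.choice(_MARKER_WORDS)} positive")
    post = f"Sharing a case: {', '.join(words)}."
    return CaseText(post_text=post, hashtags=tuple(tags))


def _largest_remainder(mix, n: int) -> np.ndarray:
    mix = np.asarray(mix, dtype=np.float64)
    raw = mix * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def _allocate(values, mix, n: int, rng: np.random.Generator) -> list:
    counts = _largest_remainder(mix, n)
    pool = [v for v, c in zip(values, counts) for _ in range(c)]
    rng.shuffle(pool)
    return pool


def _conditional_class_mix(tissue: str, cfg: SynthConfig) -> np.ndarray:
    mix = np.asarray(cfg.class_mix, dtype=np.float64)
    j = TISSUES.index(tissue)
    if cfg.tissue_class_skew == 0 or j >= 9:
        return mix
    out = mix - cfg.tissue_class_skew / 2
    out[j % 3] = mix[j % 3] + cfg.tissue_class_skew
    return np.clip(out, 0, None) / np.clip(out, 0, None).sum()


def _allocate_diseases(tissues, cfg: SynthConfig, rng: np.random.Generator) -> list:
    """Per-tissue conditional class allocation with the global class counts
    held exactly at class_mix (drift from per-cell rounding is repaired by
    deterministic reassignment)."""
    n = len(tissues)
    target = _largest_remainder(cfg.class_mix, n)
    diseases = [None] * n
    for tissue in TISSUES:
        idx = [i for i, t in enumerate(tissues) if t == tissue]
        if not idx:
            continue
        cell = _allocate(DISEASES, _conditional_class_mix(tissue, cfg), len(idx), rng)
        for i, d in zip(idx, cell):
            diseases[i] = d
    # repair rounding drift so global counts match the configured mix exactly
    counts = {d: diseases.count(d) for d in DISEASES}
    over = [d for d, t in zip(DISEASES, target) if counts[d] > t]
    under = [d for d, t in zip(DISEASES, target) if counts[d] < t]
    for d_over in over:
        while counts[d_over] > target[DISEASES.index(d_over)] and under:
            d_under = under[0]
            i = next(i for i in range(n) if diseases[i] == d_over)
            diseases[i] = d_under
            counts[d_over] -= 1
            counts[d_under] += 1
            if counts[d_under] >= target[DISEASES.index(d_under)]:
                under.pop(0)
    return diseases


def generate_dataset(cfg: SynthConfig, outdir) -> Path:
    """Write ``n_images`` rendered cases plus a ``manifest.jsonl`` with gold
    labels; returns the manifest path.  Label frequencies match the
    configured mixes exactly (largest-remainder allocation); pathologists
    are assigned round-robin (weighted when weights given)."""
    from .textlabel import CaseLabels  # local import to avoid cycle at type time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    tissues = _allocate(TISSUES, cfg.tissue_mix, cfg.n_images, rng)
    stains = _allocate(STAINS, cfg.stain_mix, cfg.n_images, rng)
    diseases = _allocate_diseases(tissues, cfg, rng)

    weights = cfg.pathologist_weights or tuple([1] * cfg.n_pathologists)
    cycle = [i for i, w in enumerate(weights) for _ in range(int(w))]
    artifacts = [
        pathologist_artifact(i, cfg.artifact_strength, cfg.seed)
        for i in range(cfg.n_pathologists)
    ]

    rows = []
    for i in range(cfg.n_images):
        case_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729, i]))
        path_idx = cycle[i % len(cycle)]
        rate = (
            cfg.marker_rate[diseases[i]]
            if isinstance(cfg.marker_rate, dict)
            else cfg.marker_rate
        )
        marker = bool(case_rng.random() < rate)
        labels = CaseLabels(
            tissue=tissues[i], disease=diseases[i], stain=stains[i],
            marker_mention=marker,
        )
        img = render_image(
            labels.disease, labels.tissue, labels.stain,
            artifacts[path_idx], case_rng, cfg,
        )
        fname = f"case_{i:04d}.png"
        iio.imwrite(outdir / fname, img)

        text_tissue = MISSING if case_rng.random() < cfg.tissue_missing_rate else labels.tissue
        text = generate_text(
            CaseLabels(
                tissue=text_tissue, disease=labels.disease, stain=labels.stain,
                marker_mention=marker,
            ),
            case_rng,
            cfg.text_noise_rate,
        )
        rows.append(
            {
                "id": f"case_{i:04d}",
                "image_path": fname,
                "text": text.post_text,
                "hashtags": list(text.hashtags),
                "pathologist_id": f"pathologist_{path_idx:02d}",
                "gold": {
                    "tissue": labels.tissue,
                    "disease": labels.disease,
                    "stain": labels.stain,
                    "marker_mention": marker,
                },
            }
        )

    manifest = outdir / "manifest.jsonl"
    with open(manifest, "w") as fh:
        for row in rows:
            fh.write(json.dumps(row) + "\n")
    return manifest


def manifest_hash(manifest_path) -> str:
    return hashlib.sha256(Path(manifest_path).read_bytes()).hexdigest()
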