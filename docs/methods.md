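# Methods

## Overview

`histoprox` implements a hybrid histopathology classifier whose decision
structure doubles as a similarity metric. A case — one photomicrograph plus
its social-media discussion text — is mapped to named feature blocks:

| block | dim | content |
|---|---|---|
| `hand2412` | 2412 | hand-engineered image features of the 512×512 center crop |
| `deepset100` | 100 | sum over 21 patches of a trainable encoder's approximately-binary head |
| `generic2048` | 2048 | sum over 21 patches of a generic pooled backbone output |
| `sift5` | 5 | bag of the 5 most prevalent SIFT descriptor clusters |
| `tissue10` | 10 | tissue-type one-hot (NaN for the forest when unknown) |
| `marker1` | 1 | marker-test mention bit (IHC, FISH, named antibodies) |

A 1000-tree Random Forest (Gini, √d candidate features per split,
bootstrap, unlimited depth, min leaf 1) is trained on the fused blocks. Two
cases that traverse the identical sequence of decisions in a tree share its
leaf; counting such trees gives a proximity in 0..1000 that ranks a corpus
by similarity to a query. Because routing is deterministic — including for
missing covariates, which follow a fixed per-split direction (the
majority branch when the split saw no missing values in training) —
"identical decision sequence" and "identical leaf" coincide.

## Image standardization

Images are gray-world white balanced (per-channel gain `global mean /
channel mean`, clipped to 8 bits), bilinearly rescaled so the short side is
exactly 512 px (long side rounded half-up), and center-cropped to 512×512
(offsets floored when odd). Coordinates are 0-based (row, col) with
half-open patch extents. Gray-world is the simplest correction consistent
with fixing a global blue cast from under-lit microscope photography; no
stain deconvolution or further color normalization is attempted.

## The 21-patch grid

The set representation samples 224×224 patches at the 25 offsets
`linspace(0, H−224, 5) × linspace(0, W−224, 5)` (rounded half-up). Four of
the 25 tiles — the odd-odd interior slots (1,1), (1,3), (3,1), (3,3) — are
not evaluated, leaving 21. This choice is forced by two requirements:
the 21 patches must span the input image entirely (corner tiles are the
only tiles covering corner pixels, so corners cannot be dropped), and
heatmaps impute exactly 4 of 25 tiles from their four nearest evaluated
neighbours — for an odd-odd interior tile those are precisely its four
grid-adjacent tiles, making the median imputation exact. Wider images
yield proportionally larger column strides, i.e. less x-overlap.

## Hand-engineered features (2412)

Fixed block order, each histogram L1-normalized so it sums to 1 when its
pixels exist (zero vector otherwise, e.g. gradient orientations of a
constant image):

* RGB histograms, 3×256; HSV histograms, 3×256; gray histogram, 256.
* Local Binary Patterns Pyramid: rotation-invariant uniform LBP with
  (P, R) ∈ {(8,1), (16,2), (24,3)} → 10+18+26 = 54 bins per level, over a
  6-level half-resolution Gaussian pyramid (512 → 16 px): 324. LBP is
  computed on the integer-quantized gray image so monotone gray shifts
  leave codes unchanged up to quantization.
* Gradient orientation histograms, 36 bins × 6 pyramid levels,
  magnitude-weighted: 216.
* Gray co-occurrence texture: 13 Haralick statistics × 4 offsets at
  distance 1, on a 64-level quantization: 52. (64 levels is standard
  practice and keeps the statistics well conditioned on a 512×512 crop;
  the 13 statistics are implemented directly since library helpers expose
  only a subset.)
* 7 Hu moment invariants on a signed-log scale.
* Mean/std/entropy for 7 channels (R, G, B, H, S, V, gray): 21.

Totals: 768+768+256+324+216+52+7+21 = 2412. The canonical feature-family
arithmetic leaves no room for a separate gradient-magnitude histogram — the
magnitude block absorbs the dimensional slack and shrinks to zero bins —
so magnitude information enters only through the weighting of the
orientation histograms. The block table is exposed programmatically
(`handfeat.BLOCK_TABLE`) and validated at import time.

SIFT descriptors come from scikit-image's difference-of-Gaussian SIFT.
The k=5 vocabulary is k-means on descriptors pooled over *training-fold*
crops only (seeded, centroids ordered most-prevalent first); the per-crop
feature is the L1-normalized 5-bin assignment histogram, zero when a crop
has no keypoints.

## Patch encoder and set representation

The trainable encoder is a compact NumPy network: a fixed descriptor
(28×28 gray block means + channel means/stds, zero image ↦ zero vector),
a 64-unit ReLU hidden layer, and a 100-unit head squashed by a steep
sigmoid `σ(τ z)` with τ = 4. Training minimizes patch-level cross-entropy
(labels inherited from the image — weak labeling) plus a binarization
penalty `λ·mean(x(1−x))` with λ = 0.01 that pushes head outputs toward
{0, 1}; both constants are exposed in `EncoderConfig`. The class head is a
softmax over the 100 head outputs concatenated with the 11 covariates
(tissue one-hot as zeros when missing, marker bit). Augmentation during
training: right-angle rotations, ±15° rotations with reflect padding,
flips, zoom 0.9–1.1, brightness 0.9–1.1, Gaussian noise σ = 2.5 (8-bit
scale), and Mixup with Beta(0.2) target mixing. Training is single-threaded
Adam with a fixed seed; identical config and data give bit-identical
weights.

An image's set representation is the elementwise sum of the 21 per-patch
head outputs (entries in [0, 21], order-invariant). The generic 2048-d
block is the analogous sum of a pluggable backbone's pooled outputs; the
default backbone is a deterministic seeded projection of the patch
descriptor through tanh, and any patch→2048 callable (e.g. a pretrained
convolutional network) can be plugged in without touching downstream code.

## Weak-supervision labels

Tissue (10 canonical types), disease state (nontumor / low grade /
malignant) and stain (H&E / IHC / other) are parsed from hashtags and
free text by editable plain-text rule tables (`pattern TAB target TAB
priority`). Hashtags are matched exactly (after `#`-stripping and
lowercasing) and take precedence; free text is matched at word boundaries;
within a text unit only the best-priority rules count, so multi-word rules
("carcinoma in situ" → low grade) beat their single-word substrings
("carcinoma" → malignant). Conflicts are resolved by majority vote across
post and replies, then priority; unresolved ties give MISSING. The marker
lexicon mixes literal terms and regexes (`cd\d+`). The shipped ~60-entry
tables are a reconstruction of a consensus keyword scheme, not a published
table; they are data files, not code.

## Evaluation protocol

* **Ten-fold CV**, stratified, over seeded replicates (seeds 0..9 by
  default); per-class one-vs-rest AUROC is combined by instance-count
  weighting: `overall = Σ count_c · AUROC_c / Σ count_c`.
* **Leave-one-pathologist-out (LOPO) search**: for each contributor, the
  forest (and any fold-fitted artifact — SIFT vocabulary, encoder — via
  the `refit` hook) is trained without that contributor's cases, the
  training corpus is indexed, and each held-out case queries it;
  precision@k (k = 1..10) is reported overall and per contributor. This
  isolates contributor-specific staining/camera artifacts from training.
* **Permutation null**: the identical LOPO pipeline with training labels
  shuffled (seeded); evaluation labels untouched. This is the chance level
  of precision@k.
* **Rank-sum comparison** of replicate sets: two-tailed Mann–Whitney with
  midrank ties; exact enumeration when tie-free and both samples ≤ 12,
  otherwise normal approximation with tie and continuity corrections. Both
  U and its complement n·m−U are reported. Exact printed p-values from
  normal-approximation software depend on tie patterns in the data, so no
  attempt is made to reproduce any specific approximate p; the exact mode
  is preferred at these sample sizes.

## Sanity checks and interpretability

Each query carries three checks: (i) **uncertainty** — trees are
bootstrapped within each ensemble member (default 200 resamples) to form an
interval for the top-minus-runner-up activation margin; the prediction is
uncertain when the 95% interval includes 0; (ii) **prediction as a check**
— if a supplied reference label disagrees with the predicted class, search
results from the same forest are suspect; (iii) **heatmaps** — per-class
softmax activations on the 5×5 grid (each tile sums to 1 after imputation
and renormalization) and per-feature head-output grids (no
renormalization), for human review. Block-aware permutation importance
(mean decrease in held-out accuracy over seeded shuffles; the 10 tissue
columns shuffled jointly as one block) ranks features, and `select_deep3`
picks the top-3 deep features (ties to the lower index).

The bootstrap-over-trees uncertainty statistic is this package's own
construction; the ensemble default is 3 members, each pairing a forest
with an independently seeded encoder feature block.

## Synthetic study design

No real corpus ships with the package; `synthgen` emulates the structure
that matters for testing the method:

* **3 disease states separable mainly by texture.** Nuclei are elliptical
  blobs; per-class defaults (lognormal radii, log-scale eccentricity):
  nontumor ~100 blobs, median radius 9.0 px, size spread 0.05, shape
  spread 0.05; low grade ~225 / 5.58 / 0.28 / 0.28; malignant ~400 /
  3.34 / 0.55 / 0.55. Blobs are stamped against a per-image chromatin
  *area budget* (a class-independent lognormal target around
  `density · π · E[r²]`, identical across the default classes), and
  eccentricity is area-preserving (axes `r·e^{±ε/2}`), so the realized
  chromatin area fraction — the dominant driver of global color and
  intensity histograms — is class-independent in both mean and spread.
  The discriminative signal is *pleomorphism* — the within-image
  dispersion of nuclear size and shape, the texture-scale expression of
  atypia — which is invariant to magnification. (The generator also
  supports per-blob tone dispersion and crowding around foci as optional
  class properties; the defaults keep them off because they load directly
  onto the large color-histogram and co-occurrence feature families,
  where they would let even an unsupervised similarity recover the
  class.)
* **Disease mix varies by tissue**, as in real corpora where some tissues
  are shared mostly for low-grade lesions and others mostly for
  malignancies: tissue j < 9 favors class j mod 3 by +0.35 (others
  −0.175), the tenth tissue is balanced, and the rotation keeps the
  global class mix exactly at the configured proportions. The supervised
  forest exploits these conditional priors through the tissue covariate;
  the label-shuffled null barely sees them (the tissue one-hot is 10 of
  2423 columns, and white balance plus exposure jitter wash the tissue
  tint out of the image features).
* **Nuisance structure mirroring an uncontrolled photo corpus**: 10
  tissue-type background tints; stain palettes (H&E pink/purple, IHC
  brown, other gray); per-pathologist tint/exposure artifacts (fixed per
  contributor); and per-image variation in magnification (lognormal,
  σ = 0.58), focus (Gaussian blur up to 1.5 px), stain depth, stromal
  texture correlation length, collagen-like fiber strands at widely
  varying density (which dominate gradient-orientation and fine-texture
  statistics), and exposure. These dominate raw
  feature-space geometry, so unsupervised similarity groups cases by
  stain/tissue/contributor rather than disease — the same qualitative
  behavior reported for real corpora, where hand-engineered features do
  not cluster by disease state and only supervised learning extracts the
  disease signal. This is also what makes the permutation null sit at the
  class prior rather than above it.
* **Marker mentions correlate with suspected malignancy** (rates 0.08 /
  0.22 / 0.50 by disease state, ~27% overall), as in real discussions
  where IHC is ordered to work up suspected cancer.
* **Text** is generated as hashtags + keywords that the default rule
  tables parse back to the generating labels (round-trip exact at zero
  noise); 5% of cases get unparseable text and 10% omit the tissue tag,
  exercising the missing-covariate path.
* Label frequencies follow the configured mixes exactly
  (largest-remainder allocation); contributors are assigned round-robin.

What the generator does **not** emulate: real chromatin texture,
within-slide spatial organization (glands, stroma architecture),
plausible pathology vocabulary beyond the rule tables, multi-panel
figures, or label noise correlated with image content. Passing tests
demonstrate that the pipeline recovers a texture-borne signal under
realistic nuisance, not that it reaches any particular accuracy on real
histopathology.

## Problem sizes and numerical choices

The default study is 300 cases and 10 contributors — large enough for
stable LOPO statistics on one CPU in minutes, the package's intended desk
scale. Full-size forests (1000 trees) are used for LOPO and its null;
500 trees for the ten-fold stain task and auxiliary fits, where AUROC has
saturated. Deterministic tie-breaks throughout: argmax takes the lowest
index, search ties break by ascending corpus id, imputation neighbour ties
row-major. All randomness flows from explicit integer seeds.

## Known limitations

* The forest backend is scikit-learn; leaf identifiers are per-tree node
  ids, portable across save/load (joblib) but not across library versions.
* The trainable encoder is a deliberately small network over fixed
  descriptors — adequate for desk-scale separable fixtures, not a
  substitute for training a deep backbone on real tissue.
* Weak-supervision rules are keyword-level; negations ("no carcinoma")
  and non-English text are out of scope.
* Proximity search cost is O(corpus × trees) per query after indexing;
  no approximate-nearest-neighbour shortcut is provided.
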