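import numpy as np
import pytest

from histoprox import synthgen, workbench


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_corpus(tmp_path_factory):
    """Small synthetic corpus: 45 cases, 3 pathologists, balanced classes."""
    outdir = tmp_path_factory.mktemp("tiny_corpus")
    cfg = synthgen.SynthConfig(n_images=45, n_pathologists=3, seed=7)
    manifest = synthgen.generate_dataset(cfg, outdir)
    cases = workbench.load_manifest(manifest)
    return cases, manifest, cfg


@pytest.fixture(scope="session")
def tiny_records(tiny_corpus):
    """Hand-engineered + covariate fused records of the tiny corpus."""
    cases, _, _ = tiny_corpus
    return workbench.extract_features(cases, ("hand2412", "tissue10", "marker1"))


@pytest.fixture(scope="session")
def tiny_forest(tiny_records):
    from histoprox import proxforest

    return proxforest.train_forest(tiny_records, n_trees=100, seed=0)


def textured_crop(seed: int = 0, n_dots: int = 120) -> np.ndarray:
    """512x512 crop with dark dots on a light field (SIFT-detectable)."""
    r = np.random.default_rng(seed)
    img = np.full((512, 512, 3), 220, dtype=np.uint8)
    for _ in range(n_dots):
        cy, cx = r.integers(10, 502, 2)
        rad = int(r.integers(3, 9))
        yy, xx = np.ogrid[-rad:rad + 1, -rad:rad + 1]
        mask = yy**2 + xx**2 <= rad**2
        patch = img[cy - rad : cy + rad + 1, cx - rad : cx + rad + 1]
        patch[mask] = r.integers(20, 80)
    return img
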