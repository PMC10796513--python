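import numpy as np
import pytest

from nisslcyto import segmentation as seg
from nisslcyto import synthetic as syn

#: two-layer column used by the image-based tests (fits a 600x500 field)
MINI_LAYERS = [
    syn.LayerSpec("I", 150.0, 250.0, (0.4, 0.3, 0.2, 0.1)),
    syn.LayerSpec("II", 150.0, 450.0, (0.25, 0.25, 0.4, 0.1)),
]


def mini_section(seed: int, touching: float = 0.0) -> syn.SectionRecord:
    spec = syn.CohortSpec(image_size=(600, 500), touching_fraction=touching,
                          seed=seed)
    return syn.render_section(MINI_LAYERS, syn.identity_effects()["adult"],
                              spec, np.random.default_rng(seed))


@pytest.fixture(scope="session")
def seg_config() -> seg.SegConfig:
    return seg.SegConfig()


@pytest.fixture(scope="session")
def rendered_section() -> syn.SectionRecord:
    """One non-touching synthetic section shared across tests."""
    return mini_section(30, touching=0.0)


@pytest.fixture(scope="session")
def trained_classifiers(seg_config):
    """Merge and false-positive classifiers fitted on touching fixtures."""
    fixtures = [mini_section(s, touching=0.25) for s in range(10, 18)]
    mc = seg.train_merge_classifier(fixtures, seg_config, seed=0)
    fc = seg.train_fp_classifier(fixtures, seg_config, seed=0,
                                 merge_classifier=mc)
    return mc, fc


@pytest.fixture(scope="session")
def archetype_samples():
    """1000 clean (irregularity 0) polygons + features per archetype."""
    import dataclasses

    rng = np.random.default_rng(123)
    out = {}
    for name, arch in syn.default_archetypes().items():
        clean = dataclasses.replace(arch, irregularity=0.0)
        polys = syn.sample_cell_polygons(clean, 1000, rng)
        out[name] = (polys, syn.polygon_morphometrics(polys))
    return out
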