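import dataclasses

import numpy as np
import pandas as pd
import pytest

import cingfp as cf
from cingfp.core_io import LabelAtlas
from cingfp.tracer import sample_density, stack_densities


@pytest.fixture(scope="session")
def atlas_default():
    """Default-sized phantom atlas (40 x 60 x 30, 9 bilateral targets)."""
    return cf.build_phantom_atlas()


@pytest.fixture(scope="session")
def atlas_small():
    """Small phantom for fast unit tests (6 bilateral targets)."""
    return cf.build_phantom_atlas((24, 40, 16), n_targets=6)


@pytest.fixture(scope="session")
def rules_small():
    """Two-zone rule set naming only targets present on atlas_small."""
    return dataclasses.replace(
        cf.default_tracer_rules(noise_sd=0.1),
        zones=(
            cf.TracerZone(0.15, 0.12, ("amygdala", "nucleus_accumbens", "orbitofrontal")),
            cf.TracerZone(0.75, 0.12, ("caudoputamen", "insula")),
        ),
    )


@pytest.fixture(scope="session")
def tracer_collection(atlas_default):
    """60 default-rule tracer experiments plus generator ground truth."""
    rules = cf.default_tracer_rules(noise_sd=0.2)
    experiments, truth = cf.simulate_tracer_experiments(
        atlas_default, rules, 60, rng_seed=0, return_truth=True
    )
    return rules, experiments, truth


@pytest.fixture(scope="session")
def similarity_default(atlas_default, tracer_collection):
    """Parcellation-scale similarity map on the default phantom."""
    _, experiments, _ = tracer_collection
    strip = atlas_default.ids_with_role("seed_roi")
    n = int(atlas_default.mask_of(strip).sum())
    seeds = cf.place_seeds(atlas_default, strip, n)
    seed_pm = sample_density(experiments, seeds.voxel_sets, list(range(n)))
    sim = cf.projection_similarity(
        seed_pm, stack_densities(experiments), atlas_default.shape
    )
    return seeds, sim


@pytest.fixture()
def straight_strip_atlas():
    """A 100-voxel single-file strip along the rostro-caudal axis."""
    labels = np.zeros((3, 100, 3), dtype=np.int32)
    labels[1, :, 1] = 1
    table = pd.DataFrame(
        {"label_id": [1], "name": ["strip"], "hemisphere": ["M"], "role": ["seed_roi"]}
    )
    return LabelAtlas(labels, table)


def naive_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Double-loop Pearson between columns of a and columns of b."""
    out = np.empty((a.shape[1], b.shape[1]))
    for i in range(a.shape[1]):
        for j in range(b.shape[1]):
            x, y = a[:, i], b[:, j]
            if x.std() == 0 or y.std() == 0:
                out[i, j] = np.nan
                continue
            out[i, j] = np.corrcoef(x, y)[0, 1]
    return out
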