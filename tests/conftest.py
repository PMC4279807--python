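import numpy as np
import pytest

import atlaslink as al


def make_sphere(grid: al.ImageGrid, center, radius_mm: float) -> al.BinaryMask:
    centers = grid.voxel_centers()
    d2 = sum((centers[..., a] - center[a]) ** 2 for a in range(3))
    return al.BinaryMask(grid, d2 <= radius_mm**2)


def random_blob(rng, shape=(12, 12, 10), spacing=(1.0, 1.0, 2.0), p=0.3) -> al.BinaryMask:
    grid = al.ImageGrid(shape, spacing)
    return al.BinaryMask(grid, rng.random(shape) < p)


@pytest.fixture(scope="session")
def phantom_spec():
    """The standard phantom: 64x64x48 voxels at 2x2x3 mm."""
    return al.PhantomSpec()


@pytest.fixture(scope="session")
def template(phantom_spec):
    return al.make_template(phantom_spec, seed=0)


@pytest.fixture(scope="session")
def standard_population(template, phantom_spec):
    """The standard seeded cohort of six atlas subjects."""
    return al.make_population(
        template, al.PopulationSpec(n_atlases=6, seed=0), organs=phantom_spec.organs
    )


@pytest.fixture(scope="session")
def standard_experiment(standard_population):
    """Leave-one-out linking experiment on the standard cohort with 2 mm RMS
    registration error: link counts 0..4 (one to five composed
    transformations), all 30 direct and 120 one-link cases enumerated, 30
    sampled chains for longer links, fused scoring included."""
    atlases = {a.atlas_id: a for a in standard_population}
    provider = al.pairwise_provider(standard_population, 2.0, seed=0)
    config = al.ExperimentConfig(
        links=(0, 1, 2, 3, 4),
        n_samples={0: 30, 1: 120, 2: 30, 3: 30, 4: 30},
        seed=11,
        include_fused=True,
    )
    return al.run_experiment(atlases, provider, config)


@pytest.fixture(scope="session")
def coarse_population():
    """A small, coarse-grid cohort (32x32x24 at 4x4x6 mm, four subjects)
    for tests that exercise plumbing rather than resolution."""
    spec = al.PhantomSpec(grid=al.ImageGrid((32, 32, 24), (4.0, 4.0, 6.0)))
    template = al.make_template(spec, seed=0)
    return al.make_population(
        template, al.PopulationSpec(n_atlases=4, seed=0), organs=spec.organs
    )
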