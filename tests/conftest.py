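"""Shared fixtures: analytic phantoms and the seeded benchmark cohort.

Everything is generated programmatically; the heavier end-to-end products
(benchmark report with ablation) are session-scoped so the three-condition
pipeline runs once for the whole suite.
"""

import pytest

from unfoldreg import (PhantomParams, CohortVariation, generate_phantom,
                       generate_cohort, compute_coordinates,
                       extract_midthickness_grid, compute_features,
                       prepare_feature_stack, run_benchmark)

TEST_GRID = (64, 32)  # reduced unfolded grid keeps the suite fast


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomParams(grid_shape=TEST_GRID), seed=1)


@pytest.fixture(scope="session")
def default_unfolding(default_phantom):
    coords = compute_coordinates(default_phantom.labels)
    grid = extract_midthickness_grid(coords, default_phantom.labels,
                                     shape=TEST_GRID)
    return coords, grid


@pytest.fixture(scope="session")
def default_stack(default_phantom, default_unfolding):
    coords, grid = default_unfolding
    stack = prepare_feature_stack(compute_features(coords, grid))
    stack.valid = stack.valid & grid.valid
    return stack


def _flat_params(**kw):
    base = dict(curl_angle_rad=0.0, n_gyri=0, gyral_amplitude_mm=0.0,
                thickness_profile=(2.0,) * 5, thickness_smooth_mm=0.0,
                thickness_ap_taper=0.0, grid_shape=TEST_GRID)
    base.update(kw)
    return PhantomParams(**base)


@pytest.fixture(scope="session")
def flat_slab():
    """Flat uncurled sheet of uniform 2 mm thickness (analytic oracle)."""
    sample = generate_phantom(_flat_params(), seed=1)
    coords = compute_coordinates(sample.labels)
    grid = extract_midthickness_grid(coords, sample.labels, shape=TEST_GRID)
    return sample, coords, grid


@pytest.fixture(scope="session")
def cylinder_shell():
    """Uniform-curvature shell with curl radius 10 mm (arc 20 mm, 2 rad)."""
    params = _flat_params(curl_angle_rad=2.0,
                          curl_profile=(1.0,) * 5)
    sample = generate_phantom(params, seed=1)
    coords = compute_coordinates(sample.labels)
    grid = extract_midthickness_grid(coords, sample.labels, shape=TEST_GRID)
    return sample, coords, grid


@pytest.fixture(scope="session")
def cohort7():
    """The benchmark cohort: seven jittered phantoms, 4 left / 3 right."""
    return generate_cohort(7, PhantomParams(grid_shape=TEST_GRID),
                           CohortVariation(), seed=42)


@pytest.fixture(scope="session")
def benchmark_report(cohort7):
    """Three-condition benchmark plus feature ablation on the cohort."""
    return run_benchmark(cohort7, ref_index=0, grid_shape=TEST_GRID,
                         with_ablation=True)
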