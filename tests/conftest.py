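import numpy as np
import pytest

from secondrisk import CohortSpec, DoseGrid, OrganMask, generate_cohort

COARSE_SPACING = (5.0, 5.0, 5.0)
COARSE_SHAPE = (60, 60, 40)


def coarse_cohort_spec(n_patients: int = 26) -> CohortSpec:
    """Cohort at 5 mm resolution (same 300x300x200 mm volume) for speed."""
    return CohortSpec(n_patients=n_patients, spacing_mm=COARSE_SPACING, shape=COARSE_SHAPE)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient coarse cohort shared across pipeline tests."""
    return generate_cohort(coarse_cohort_spec(6), seed=11)


@pytest.fixture
def uniform_grid():
    """5x5x5 grid at a uniform 2 Gy with a full mask."""
    grid = DoseGrid(np.full((5, 5, 5), 2.0), (2.0, 2.0, 2.0))
    mask = OrganMask(np.ones((5, 5, 5), dtype=bool), "organ")
    return grid, mask


def random_dvh(rng, n_bins=40, bin_width=0.5, organ="organ"):
    """Random differential DVH with at least one occupied bin."""
    from secondrisk import DifferentialDVH

    edges = np.arange(n_bins + 1) * bin_width
    volumes = rng.uniform(0.0, 10.0, size=n_bins)
    volumes[rng.integers(n_bins)] += 1.0  # guarantee V0 > 0
    return DifferentialDVH(edges, volumes, organ)
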