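import numpy as np
import pytest

from gfqmdr import GenotypeMatrix, IntervalScheme, build_equal_length_scheme


@pytest.fixture
def unit_scheme() -> IntervalScheme:
    """Equal-width three-level scheme on [0, 3]: midpoints 0.5, 1.5, 2.5."""
    return build_equal_length_scheme(np.array([0.0, 3.0]), J=3)


@pytest.fixture
def midpoint_fixture(unit_scheme):
    """Dataset whose trait values sit exactly on interval midpoints.

    Marker 0 perfectly determines the trait level (code -> level code+1);
    marker 1 is irrelevant.  On such data every fuzzy count collapses to an
    integer count, so all scoring methods must agree exactly.
    """
    rng = np.random.default_rng(42)
    codes0 = np.repeat([0, 1, 2], 12)
    codes1 = rng.integers(0, 3, size=codes0.size)
    codes = np.column_stack([codes0, codes1])
    trait = unit_scheme.midpoints[codes0]
    return GenotypeMatrix(codes=codes), trait, unit_scheme


def random_instance(rng: np.random.Generator, n: int, m: int):
    """Small random genotype/trait instance for oracle comparisons."""
    codes = rng.integers(0, 3, size=(n, m))
    trait = rng.normal(size=n)
    return GenotypeMatrix(codes=codes), trait
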