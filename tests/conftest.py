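import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from promshape import (
    ExtractionConfig,
    FeatureMatrix,
    SignalConfig,
    build_matrix,
    make_bundle,
)
from promshape.shape import PentamerTable


@pytest.fixture
def tiny_genome():
    return {"chr1": "ACGTACGTACGT"}


@pytest.fixture
def const_table():
    """Pentamer table where every value of every pentamer is 5.0."""
    return PentamerTable(np.full((1024, 6), 5.0))


def random_table(rng: np.random.Generator) -> PentamerTable:
    """Unstructured random table (no GC trend, no symmetry): oracle fodder."""
    values = np.column_stack(
        [
            rng.uniform(3, 7, 1024),
            rng.uniform(-18, 0, 1024),
            rng.uniform(-8, 8, 1024),
            rng.uniform(-8, 8, 1024),
            rng.uniform(30, 40, 1024),
            rng.uniform(30, 40, 1024),
        ]
    )
    return PentamerTable(values)


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic experiment shared across tests."""
    return make_bundle(SignalConfig(n_pos=60, n_neg=120, n_chrom=6, seed=777))


@pytest.fixture(scope="session")
def small_core_matrix(small_bundle) -> FeatureMatrix:
    config = ExtractionConfig(groups=("sequence", "gc", "shape"))
    return build_matrix(
        small_bundle.variants,
        small_bundle.genome,
        small_bundle.pentamers,
        small_bundle.tracks,
        config,
    )
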