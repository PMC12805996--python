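import numpy as np
import pytest

from ramanqa import (
    Ramanome,
    make_species_cohort,
    simulate_cells,
)
from ramanqa.preprocess import PreprocessConfig, preprocess_pipeline


def combine(rams):
    """Concatenate per-species ramanomes sharing one axis."""
    cells = tuple(c for r in rams for c in r.cells)
    return Ramanome(rams[0].axis, cells)


@pytest.fixture(scope="session")
def small_cohort():
    """Two well-separated synthetic species."""
    return make_species_cohort(2, seed=7)


@pytest.fixture(scope="session")
def separable_pair(small_cohort):
    """200 cells/species, preprocessed; linearly separable by construction."""
    rams = [
        simulate_cells(s, 200, seed=30 + i, batch_id="b1")
        for i, s in enumerate(small_cohort)
    ]
    processed, _ = preprocess_pipeline(combine(rams), PreprocessConfig(), normalize=False)
    return processed


@pytest.fixture(scope="session")
def four_species_small():
    """4 species x 150 cells, preprocessed; used by several classify tests."""
    cohort = make_species_cohort(4, seed=21)
    rams = [simulate_cells(s, 150, seed=50 + i) for i, s in enumerate(cohort)]
    processed, _ = preprocess_pipeline(combine(rams), PreprocessConfig(), normalize=False)
    return processed
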