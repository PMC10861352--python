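import numpy as np
import pytest

from protopanel import (
    CohortDesign,
    compute_marker_stats,
    log2_standardize,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """10/10 subjects, 60 markers, two planted effects at 2.5 SD."""
    design = CohortDesign(
        n_case=10, n_control=10, p=60, true_markers=(0, 1),
        delta=2.5, seed=11,
    )
    matrix, labels = simulate_cohort(design)
    return matrix, labels


@pytest.fixture(scope="session")
def std_small(small_cohort):
    matrix, labels = small_cohort
    return log2_standardize(matrix), labels


@pytest.fixture(scope="session")
def small_stats(std_small):
    std, labels = std_small
    return compute_marker_stats(std, labels)
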