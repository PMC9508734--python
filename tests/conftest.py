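import pytest

from telotype.insertions import ExclusionRegions
from telotype.simulate import (
    SimConfig,
    default_exclusion_intervals,
    make_reference,
    simulate_wgs_pair,
)


@pytest.fixture(scope="session")
def small_reference():
    return make_reference(seed=11)


@pytest.fixture(scope="session")
def exclusions(small_reference):
    return ExclusionRegions.from_intervals(
        default_exclusion_intervals(small_reference)
    )


@pytest.fixture(scope="session")
def wgs_with_insertions(small_reference):
    """Tumor/normal pair with three planted insertion sites that all
    meet the caller thresholds (>= 3 pairs, >= 2 clips)."""
    cfg = SimConfig(
        seed=11,
        n_reads=8000,
        telomeric_fraction=5e-4,
        insertion_sites=(
            ("chr1", 10_500, 4, 3),
            ("chr1", 33_210, 3, 2),
            ("chr2", 20_777, 5, 4),
        ),
    )
    tumor, normal, truth = simulate_wgs_pair(cfg, small_reference)
    return cfg, tumor, normal, truth
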