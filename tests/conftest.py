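import numpy as np
import pytest

from ctdnakit import (
    CallerConfig,
    SimConfig,
    design_amplicons,
    make_reference,
)


@pytest.fixture(scope="session")
def reference8():
    """Eight 400 bp loci with one target SNV each, plus amplicon designs."""
    reference, alleles = make_reference(8, 400, seed=11)
    amplicons, failures = design_amplicons(reference, alleles)
    assert not failures
    return reference, alleles, amplicons


@pytest.fixture(scope="session")
def small_sim_config():
    """Light-depth simulator settings for fast unit tests."""
    return SimConfig(seed=3, reads_per_library=8_000, mean_reads_per_molecule=20.0)


@pytest.fixture()
def clean_sim_config():
    """Error-free, full-capture settings for exact-accounting tests."""
    return SimConfig(
        seed=5,
        seq_error_rate=0.0,
        prep_error_rate=0.0,
        capture_efficiency=1.0,
        mean_reads_per_molecule=5.0,
        reads_per_library=None,
    )


@pytest.fixture()
def exact_caller_config():
    """Caller settings for exact molecule accounting (no merging/size filter)."""
    return CallerConfig(min_reads=1, umi_merge_distance=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
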