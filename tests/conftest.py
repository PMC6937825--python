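import pytest

from nanochrom.simulate import SimParams, make_worked_example, simulate_genome, simulate_long_reads


@pytest.fixture(scope="session")
def worked_example():
    """Deterministic nine-isoform, two-locus worked example."""
    return make_worked_example()


@pytest.fixture(scope="session")
def small_truth():
    """Error-free 10-family genome with uniform copy number."""
    params = SimParams(n_chromosomes=10, seed=11, copy_number_log_sd=0.0,
                       long_error_rate=0.0, isoform_fraction=0.3)
    return simulate_genome(params)


@pytest.fixture(scope="session")
def small_reads(small_truth):
    return simulate_long_reads(small_truth, depth=10)
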