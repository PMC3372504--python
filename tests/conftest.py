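import numpy as np
import pytest

import polpause as pp
from polpause import coverage as cov

SCENARIO_SEED = 1
SCENARIO_GENES = 200


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic experiment: 200 genes (half core-histone-like with a
    250-bp decay, half poly(A)+-like with a 1500-bp decay), ~200 reads/gene."""
    return pp.simulate_scenario(n_genes=SCENARIO_GENES, seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def tracks(scenario):
    sizes = scenario.chrom_sizes
    sig = cov.build_coverage(
        cov.extend_reads(scenario.reads["polii"], 200, sizes), 50, sizes, normalization="rpm"
    )
    mock = cov.build_coverage(
        cov.extend_reads(scenario.reads["mock"], 200, sizes), 50, sizes, normalization="rpm"
    )
    return sig, mock


@pytest.fixture(scope="session")
def eag_matrices(scenario, tracks):
    sig, mock = tracks
    ms = cov.anchor_matrix(sig, scenario.genes, "EAG", 4000)
    mm = cov.anchor_matrix(mock, scenario.genes, "EAG", 4000)
    return ms, mm


@pytest.fixture(scope="session")
def pause_metrics_table(scenario, tracks, eag_matrices):
    from polpause import pause_metrics as pm

    sig, _ = tracks
    ms, mm = eag_matrices
    return pm.compute_pause_metrics(ms, mm, sig, scenario.genes)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
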