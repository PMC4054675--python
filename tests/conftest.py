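"""Shared fixtures: small synthetic datasets and helpers."""

import numpy as np
import pytest

from seedscope import (
    GenomeSource,
    RunConfig,
    SimTruth,
    build_profile,
    detect_clusters,
    run_parma,
    simulate_dataset,
)


def make_read(chrom, strand, start, seq, count=1, conversions=(), untrimmed=False,
              experiment=None, blocks=None):
    """Convenience constructor for unspliced (or custom-block) reads."""
    from seedscope import AlignedRead

    if blocks is None:
        blocks = ((start, start + len(seq)),)
    return AlignedRead(
        chrom=chrom, strand=strand, blocks=tuple(blocks), sequence=seq,
        count=count, conversions=frozenset(conversions), mismatches=0,
        untrimmed=untrimmed, experiment=experiment,
    )


@pytest.fixture(scope="session")
def sim_small():
    """120 simulated clusters: enough signal for recovery at low cost."""
    data = simulate_dataset(SimTruth(seed=7), n_clusters=120)
    genome = GenomeSource.from_dict(data.genome)
    clusters = detect_clusters(data.experiments)
    for c in clusters:
        build_profile(c, genome)
    return data, genome, clusters


@pytest.fixture(scope="session")
def sim_small_result(sim_small):
    data, genome, clusters = sim_small
    result = run_parma(clusters, RunConfig(min_pair_support=5))
    return data, clusters, result


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
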