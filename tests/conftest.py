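import numpy as np
import pytest

from loopmark.simulate import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down cohort used by fast structural tests."""
    return GeneratorConfig(
        seed=7,
        n_genes=60,
        n_probes=150,
        n_pets=60,
        n_patients=80,
        n_paired_normals=40,
        n_planted_pairs=5,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """One cohort at the study's default conditions."""
    return generate(GeneratorConfig(seed=11))


def brute_force_overlap_hits(intervals, query):
    """Quadratic oracle: all stored intervals overlapping the query."""
    return [
        iv
        for iv in intervals
        if iv.chrom == query.chrom
        and max(iv.start, query.start) < min(iv.end, query.end)
    ]


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2")):
    from loopmark.intervals import GenomicInterval

    starts = rng.integers(0, 1_000_000, size=n)
    widths = rng.integers(1, 5_000, size=n)
    names = rng.choice(chroms, size=n)
    return [
        GenomicInterval(str(names[i]), int(starts[i]), int(starts[i] + widths[i]))
        for i in range(n)
    ]
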