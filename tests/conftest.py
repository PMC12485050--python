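import numpy as np
import pytest

from refforge import synthfix
from refforge.core_io import GenomeSequence


@pytest.fixture(scope="session")
def toy_backbone():
    return [GenomeSequence("chr1", "ATTTG")]


@pytest.fixture(scope="session")
def population_bundle():
    """H=6 bundle with untied carrier counts (no 3-of-6 sites), mixing
    SNVs and indels across the frequency range."""
    sites = []
    kinds = ("snv", "ins", "del")
    carriers = (1, 2, 4, 5, 6)
    for i in range(25):
        sites.append(
            synthfix.SiteSpec(
                rel_pos=(i + 1) / 27,
                carriers=carriers[i % len(carriers)],
                kind=kinds[i % 3],
                size=1 + i % 3,
            )
        )
    cfg = synthfix.PopulationConfig(
        genome_length=30_000, n_chromosomes=2, H=6, site_spec=sites, seed=11
    )
    return synthfix.simulate_population(cfg)


@pytest.fixture(scope="session")
def planted_marker_genome():
    rng = np.random.default_rng(21)
    genome = synthfix.random_genome(60_000, 2, 0.41, rng)
    return synthfix.plant_sts_markers(genome, 20, seed=22)
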