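import numpy as np
import pytest

from stat5kit.core_io import TagCollection, parse_site_tables
from stat5kit.synthetic import generate_genome, plant_sites, simulate_tags

DEMO_SITES = {"equal": 8, "A-dom": 3, "B-dom": 3, "A-sp": 3, "B-sp": 3}

TRUTH_TO_SITE_LABEL = {
    "equal": "equal",
    "A-dom": "A-dominant",
    "B-dom": "B-dominant",
    "A-sp": "A-specific",
    "B-sp": "B-specific",
}


@pytest.fixture(scope="session")
def fixture_records():
    """The 36 published binding-site rows joined with their q-scores."""
    return parse_site_tables()


def simulate_experiment(seed, n_per_class=None, genome_length=2_000_000):
    """One full synthetic experiment: genome, site truths, A/B/input tags."""
    n_per_class = n_per_class or DEMO_SITES
    genome = generate_genome(genome_length, seed=seed)
    genome, sites = plant_sites(genome, n_per_class, seed=seed + 1)
    lengths = {c: len(s) for c, s in genome.items()}
    tags = {
        factor: simulate_tags(sites, factor, lengths, seed=seed * 10 + i)
        for i, factor in enumerate(("A", "B", "input"))
    }
    return genome, sites, tags


@pytest.fixture(scope="session")
def small_experiment():
    """A single seeded experiment shared by read-only peak/classify tests."""
    return simulate_experiment(seed=42)


def uniform_tags(n, length, seed, chrom="chr1"):
    rng = np.random.default_rng(seed)
    return TagCollection(
        {chrom: length}, {chrom: rng.integers(0, length, size=n, dtype=np.int64)}
    )
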