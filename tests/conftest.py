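import numpy as np
import pytest

from magscope import synthetic_community as syn


def three_genome_spec(seed=1, n_genes=120, n_samples=20, noise=0.05):
    return syn.CommunitySpec(
        genomes=(
            syn.GenomeModel("gA", 0.30, 150_000, n_genes),
            syn.GenomeModel("gB", 0.50, 150_000, n_genes),
            syn.GenomeModel("gC", 0.65, 150_000, n_genes, is_target_taxon=True),
        ),
        n_samples=n_samples,
        gene_noise_cv=noise,
        seed=seed,
    )


@pytest.fixture(scope="session")
def community():
    """A small 3-genome community with markers and taxonomy planted."""
    com = syn.simulate_community(three_genome_spec(), mean_contig_len=3_000, min_contig_len=1_000)
    com.marker_hits = syn.plant_marker_families(com.truth, n_families=107, seed=1)
    syn.annotate_taxa(com, seed=1)
    return com


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_sequence(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
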