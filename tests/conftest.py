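import pytest

from snpchar import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=42, n_genes=10, codon_length_range=(40, 80),
                     snps_per_gene=4.0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A session-wide small synthetic dataset (deterministic, seed 42)."""
    return generate_dataset(small_config)


def make_orf_with_codon(gene_id, n_codons, codon, codon_index):
    """Build a valid ORF (ATG ... stop) with a chosen codon at a 1-based index."""
    from snpchar import OrfSequence
    filler = "GGC"  # glycine, never a stop
    codons = ["ATG"] + [filler] * (n_codons - 2) + ["TAA"]
    codons[codon_index - 1] = codon
    return OrfSequence(gene_id, "".join(codons))
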