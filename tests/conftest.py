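import pytest

from plastcompare.synthetic import SyntheticConfig, generate_pair


@pytest.fixture(scope="session")
def synthetic_pair():
    """Default desk-scale synthetic plastome pair with ground truth."""
    return generate_pair(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def cds_pairs(synthetic_pair):
    """Homologous (gene, copy, cdsA, cdsB) tuples from the synthetic pair."""
    from plastcompare.genome_io import extract_cds

    genome_a, genome_b, annot_a, annot_b, _ = synthetic_pair
    cds_a = {(g, c): s for g, c, s in extract_cds(genome_a, annot_a)}
    cds_b = {(g, c): s for g, c, s in extract_cds(genome_b, annot_b)}
    assert set(cds_a) == set(cds_b)
    return [(g, c, cds_a[(g, c)], cds_b[(g, c)]) for (g, c) in sorted(cds_a)]
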