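"""Synthetic plastome-pair generator: determinism, construction, planting."""

import numpy as np
import pytest

from plastcompare.errors import SpecError
from plastcompare.genome_io import reverse_complement
from plastcompare.synthetic import (
    SnpSpec,
    SsrPlantSpec,
    SyntheticConfig,
    generate_pair,
    plant_ssrs,
)


def test_same_seed_is_byte_identical():
    a1, b1, _, _, t1 = generate_pair(SyntheticConfig(seed=42))
    a2, b2, _, _, t2 = generate_pair(SyntheticConfig(seed=42))
    assert a1.sequence == a2.sequence
    assert b1.sequence == b2.sequence
    assert t1 == t2


def test_different_seed_changes_background():
    a1, *_ = generate_pair(SyntheticConfig(seed=1))
    a2, *_ = generate_pair(SyntheticConfig(seed=2))
    assert a1.sequence != a2.sequence


def test_empty_mutation_spec_gives_identical_genomes():
    cfg = SyntheticConfig(snp_spec=[], indel_spec=[], seed=3)
    genome_a, genome_b, _, _, truth = generate_pair(cfg)
    assert genome_a.sequence == genome_b.sequence
    assert truth.snps == [] and truth.indels == []


def test_ira_is_reverse_complement_of_irb():
    genome_a, genome_b, _, _, truth = generate_pair(SyntheticConfig(seed=4))
    for genome, part in ((genome_a, truth.partition_a), (genome_b, truth.partition_b)):
        irb = genome.sequence[slice(*part["IRb"])]
        ira = genome.sequence[slice(*part["IRa"])]
        assert ira == reverse_complement(irb)


def test_region_lengths_respected():
    cfg = SyntheticConfig(region_lengths=(8000, 2000, 1200), seed=5)
    genome_a, _, _, _, truth = generate_pair(cfg)
    assert genome_a.length == 8000 + 2 * 2000 + 1200 == cfg.total_length
    assert truth.partition_a["LSC"] == (0, 8000)
    assert truth.partition_a["IRa"] == (11200, 13200)


def test_single_planted_snp_appears_in_truth_and_sequence():
    cfg = SyntheticConfig(
        snp_spec=[SnpSpec("gene01", 3, "transition", "synonymous")],
        indel_spec=[],
        seed=6,
    )
    genome_a, genome_b, _, _, truth = generate_pair(cfg)
    assert len(truth.snps) == 1
    snp = truth.snps[0]
    assert snp.coding_effect == "synonymous"
    diffs = [
        i for i, (x, y) in enumerate(zip(genome_a.sequence, genome_b.sequence))
        if x != y
    ]
    assert diffs == [snp.genome_a_position]


def test_infeasible_snp_spec_raises_with_entry():
    # a synonymous change at codon position 2 is impossible in the
    # standard code (no amino acid tolerates a middle-base change)
    bad = SnpSpec("gene01", 2, "transition", "synonymous")
    with pytest.raises(SpecError, match="gene01"):
        generate_pair(SyntheticConfig(snp_spec=[bad], seed=7))


def test_unknown_gene_in_spec_rejected():
    with pytest.raises(SpecError, match="nope"):
        generate_pair(
            SyntheticConfig(
                snp_spec=[SnpSpec("nope", 1, "transition", "nonsynonymous")],
                seed=8,
            )
        )


def test_ir_gene_snps_mirror_into_both_copies():
    _, _, _, _, truth = generate_pair(SyntheticConfig(seed=9))
    ir = [s for s in truth.snps if s.gene == "geneIR"]
    by_copy = {s.copy_index for s in ir}
    assert by_copy == {0, 1}
    pos0 = sorted(s.gene_position for s in ir if s.copy_index == 0)
    pos1 = sorted(s.gene_position for s in ir if s.copy_index == 1)
    assert pos0 == pos1


def test_plant_ssrs_simple_and_compound():
    seq = "G" * 400
    out, planted = plant_ssrs(
        seq,
        [("A", 13, 50), ("T", 10, 150, "CTCTCCTA"), ("AT", 6, 300)],
        rng=np.random.default_rng(0),
    )
    assert out[50:63] == "A" * 13
    assert out[150:160] == "T" * 10
    assert out[168:178] == "T" * 10
    assert out[300:312] == "AT" * 6
    spans = [(p["start"], p["end"]) for p in planted]
    assert spans == [(50, 63), (150, 160), (168, 178), (300, 312)]
    # compound span covers 28 bp
    assert planted[2]["end"] - planted[1]["start"] == 28


def test_plant_ssrs_overlap_rejected():
    with pytest.raises(SpecError):
        plant_ssrs("G" * 100, [("A", 10, 20), ("T", 10, 25)])


def test_truth_ssr_coordinates_valid_in_both_genomes(synthetic_pair):
    genome_a, genome_b, _, _, truth = synthetic_pair
    for t in truth.ssrs:
        run = t.motif * t.repeats
        assert genome_a.sequence[t.start_a - 1 : t.end_a] == run
        assert genome_b.sequence[t.start_b - 1 : t.end_b] == run


def test_default_truth_mirrors_published_class_mix(synthetic_pair):
    """24 coding SNPs: 12 Ts (8 A<->G, 4 C<->T), 12 Tv, 18 nonsyn, 6 syn."""
    *_, truth = synthetic_pair
    assert len(truth.snps) == 24
    ts = [s for s in truth.snps if s.substitution_class == "transition"]
    assert len(ts) == 12
    assert sum(s.ts_subtype == "A<->G" for s in ts) == 8
    assert sum(s.ts_subtype == "C<->T" for s in ts) == 4
    assert sum(s.coding_effect == "synonymous" for s in truth.snps) == 6


def test_full_scale_config_generates_and_partitions():
    from plastcompare.ir_structure import find_inverted_repeats
    from plastcompare.synthetic import full_scale_config

    genome_a, _, _, _, truth = generate_pair(full_scale_config(seed=10))
    assert genome_a.length == 140_000
    part = find_inverted_repeats(genome_a)
    assert (part.lsc.start, part.lsc.end) == truth.partition_a["LSC"]
    assert (part.irb.start, part.irb.end) == truth.partition_a["IRb"]
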