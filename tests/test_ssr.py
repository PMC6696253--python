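"""Perfect-SSR scanning against a brute-force oracle; compound joining."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastcompare.ssr import (
    PRESETS,
    SsrPreset,
    classify_motifs,
    compound_spans,
    find_ssrs,
    join_compounds,
    normalize_motif_class,
)


# ---------------------------------------------------------------------------
# brute-force oracle


def _oracle_find(seq, thresholds):
    """Quadratic scan: maximal full-unit tandem runs, minimal-period
    motifs, smaller unit wins on overlap."""
    n = len(seq)
    found = []
    for u in range(1, 7):
        for i in range(n - u + 1):
            unit = seq[i : i + u]
            if "N" in unit:
                continue
            # minimal period of the unit
            if any(
                u % p == 0 and unit == unit[:p] * (u // p)
                for p in range(1, u)
            ):
                continue
            # base-level left-maximal: skip rotated phases of one locus
            if i > 0 and seq[i - 1] == seq[i + u - 1]:
                continue
            j = i + u
            while j + u <= n and seq[j : j + u] == unit:
                j += u
            reps = (j - i) // u
            if reps >= thresholds[u]:
                found.append((u, i + 1, j, unit, reps))
    kept = []
    for u, s, e, unit, reps in sorted(found):
        if any(
            s <= ke and ks <= e for ku, ks, ke, *_ in kept if ku < u
        ):
            continue
        kept.append((u, s, e, unit, reps))
    return sorted((s, e, unit, reps) for _, s, e, unit, reps in kept)


@pytest.mark.parametrize("preset_name", ["strict", "melotto_modified", "relaxed"])
@pytest.mark.parametrize("seed", [0, 1])
def test_scanner_matches_brute_force_oracle_on_random_sequence(preset_name, seed):
    rng = np.random.default_rng(seed)
    # AT-rich composition encourages repeats, as in plastomes
    seq = "".join(rng.choice(list("ACGT"), p=[0.35, 0.15, 0.15, 0.35], size=10_000))
    preset = PRESETS[preset_name]
    got = sorted((r.start, r.end, r.motif, r.repeats) for r in find_ssrs(seq, preset))
    assert got == _oracle_find(seq, preset.thresholds)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=0, max_size=300))
def test_scanner_matches_oracle_on_arbitrary_short_sequences(seq):
    preset = PRESETS["relaxed"]
    got = sorted((r.start, r.end, r.motif, r.repeats) for r in find_ssrs(seq, preset))
    assert got == _oracle_find(seq, preset.thresholds)


def test_mononucleotide_run_found_with_exact_coordinates():
    seq = "CC" + "A" * 13 + "GG"
    (rec,) = find_ssrs(seq, "strict")
    assert (rec.motif, rec.repeats, rec.start, rec.end, rec.size) == ("A", 13, 3, 15, 13)


def test_run_below_threshold_not_reported():
    assert find_ssrs("G" + "A" * 9 + "G", "strict") == []


def test_dinucleotide_run():
    (rec,) = find_ssrs("CC" + "AT" * 6 + "GG", "strict")
    assert (rec.motif, rec.repeats, rec.size) == ("AT", 6, 12)


def test_dinucleotide_run_attributed_to_smallest_unit():
    # ATATATATATAT is one 2-mer SSR, never six 1-mer pairs, and an A-run
    # is never reported as an AA 2-mer
    records = find_ssrs("G" + "AT" * 6 + "G" + "A" * 12 + "G", "relaxed")
    assert [(r.motif, r.repeats) for r in records] == [("AT", 6), ("A", 12)]


def test_preset_relaxation_is_monotone():
    """Relaxing thresholds never loses SSRs (the direction behind the
    30 -> 189 -> 477 growth across survey parameterizations)."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), p=[0.35, 0.15, 0.15, 0.35], size=20_000))
    n_strict = len(find_ssrs(seq, "strict"))
    n_melotto = len(find_ssrs(seq, "melotto_modified"))
    n_relaxed = len(find_ssrs(seq, "relaxed"))
    # strict is dominated by both looser presets per unit size except the
    # mononucleotide threshold shared with 'relaxed'
    assert n_strict <= n_melotto
    assert n_strict <= n_relaxed


def test_invalid_preset_thresholds_rejected():
    with pytest.raises(ValueError):
        SsrPreset("bad", {1: 10})
    with pytest.raises(ValueError):
        SsrPreset("bad", {1: 0, 2: 5, 3: 4, 4: 3, 5: 2, 6: 2})


# ---------------------------------------------------------------------------
# compounds


def test_compound_two_polyt_runs_with_8bp_gap():
    seq = "G" + "T" * 10 + "CTCTCCTA" + "T" * 10 + "G"
    records = join_compounds(find_ssrs(seq, "strict"))
    assert len(records) == 2
    assert all(r.compound_id == "C1" for r in records)
    spans = compound_spans(records)
    assert spans["C1"][2] == 28


def test_compound_with_45bp_gap_spans_65bp(synthetic_pair):
    genome_a, _, _, _, truth = synthetic_pair
    records = join_compounds(find_ssrs(genome_a.sequence, "strict"))
    spans = compound_spans(records)
    assert sorted(s[2] for s in spans.values()) == [28, 65]


_SPACER = ("ACGTTGCA" * 20)[:150]  # period 8: holds no 1-6 bp SSR run


def test_distant_ssrs_not_joined():
    seq = "G" + "A" * 10 + _SPACER + "A" * 10 + "G"
    records = join_compounds(find_ssrs(seq, "strict"), max_gap=100)
    assert len(records) == 2
    assert all(r.compound_id is None for r in records)


def test_constituents_counted_individually():
    # 2 simple runs + a 2-part compound = 4 SSR records in total
    seq = (
        "G" + "A" * 10 + _SPACER
        + "T" * 10 + "CTCTCCTA" + "T" * 10
        + _SPACER + "G" * 10 + "C"
    )
    records = join_compounds(find_ssrs(seq, "strict"))
    assert len(records) == 4
    assert sum(r.compound_id is not None for r in records) == 2


# ---------------------------------------------------------------------------
# motif classes


def test_motif_class_merges_complement():
    assert normalize_motif_class("A") == "A/T"
    assert normalize_motif_class("T") == "A/T"
    assert normalize_motif_class("G") == "C/G"


def test_motif_class_merges_rotation():
    assert normalize_motif_class("AT") == normalize_motif_class("TA")
    assert normalize_motif_class("AAG") == normalize_motif_class("AGA")
    assert normalize_motif_class("AAG") == normalize_motif_class("CTT")


def test_class_counts():
    records = find_ssrs("C" + "A" * 10 + "C" * 3 + "T" * 10 + "ACGT" * 10 + "G" * 10 + "C", "strict")
    by_class, by_unit = classify_motifs(records)
    assert by_class == {"A/T": 2, "C/G": 1}
    assert by_unit == {1: 3}


def test_empty_input_gives_empty_counts():
    assert classify_motifs([]) == ({}, {})


def test_planted_ssrs_recovered_exactly(synthetic_pair):
    genome_a, genome_b, _, _, truth = synthetic_pair
    for genome, key in ((genome_a, "a"), (genome_b, "b")):
        found = {
            (r.motif, r.repeats, r.start, r.end)
            for r in find_ssrs(genome.sequence, "strict")
        }
        planted = {
            (t.motif, t.repeats, getattr(t, f"start_{key}"), getattr(t, f"end_{key}"))
            for t in truth.ssrs
        }
        assert planted <= found
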