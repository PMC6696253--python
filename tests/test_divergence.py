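"""Nucleotide diversity, K2P and NG86 Ka/Ks against independent oracles."""

import math
from itertools import permutations

import numpy as np
import pytest
from Bio.Data.CodonTable import unambiguous_dna_by_id

from plastcompare.divergence import (
    classify_selection,
    detect_hotspots,
    k2p_distance,
    ng86_kaks,
    sliding_pi,
)
from plastcompare.errors import IntegrityError, SaturationError
from plastcompare.genome_io import reverse_complement

# ---------------------------------------------------------------------------
# sliding Pi


def _naive_pi(columns, window, step):
    """Per-window p-distance recomputed by a direct per-site loop."""
    sites = [(a, b) for a, b in columns if a != "-"]
    out = []
    for start in range(0, len(sites), step):
        chunk = sites[start : start + window]
        valid = [
            (a, b) for a, b in chunk
            if a in "ACGT" and b in "ACGT" and "-" not in (a, b)
        ]
        diffs = sum(a != b for a, b in valid)
        out.append(None if not valid else diffs / len(valid))
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_sliding_pi_equals_naive_per_site_loop(seed):
    rng = np.random.default_rng(seed)
    alphabet = list("ACGT") + ["N", "-"]
    columns = [
        (rng.choice(alphabet, p=[0.22] * 4 + [0.06, 0.06]),
         rng.choice(alphabet, p=[0.22] * 4 + [0.06, 0.06]))
        for _ in range(2500)
    ]
    track = sliding_pi(columns, window=600, step=200)
    naive = _naive_pi(columns, 600, 200)
    assert [w.pi for w in track] == naive


def test_identical_pair_gives_zero_pi_everywhere():
    columns = [("A", "A")] * 1000
    assert all(w.pi == 0 for w in sliding_pi(columns))


def test_three_mismatches_in_full_window():
    columns = [("A", "A")] * 597 + [("A", "C")] * 3
    track = sliding_pi(columns, window=600, step=200)
    assert track[0].pi == pytest.approx(0.005)


def test_window_tiling_and_partial_flagging():
    columns = [("A", "A")] * 1000
    track = sliding_pi(columns, window=600, step=200)
    starts = [w.window_start for w in track]
    assert starts == [0, 200, 400, 600, 800]
    assert [w.partial for w in track] == [False, False, False, True, True]


def test_gap_and_n_columns_excluded_from_both_counts():
    columns = [("A", "A")] * 10 + [("A", "-")] * 5 + [("N", "C")] * 5
    (w,) = sliding_pi(columns, window=20, step=20)
    assert (w.valid_sites, w.differences) == (10, 0)


def test_window_with_zero_valid_sites_reports_undefined():
    (w,) = sliding_pi([("A", "-")] * 10, window=10, step=10)
    assert w.pi is None


# ---------------------------------------------------------------------------
# hotspots


def test_all_zero_track_has_no_hotspots():
    track = sliding_pi([("A", "A")] * 2000)
    assert detect_hotspots(track) == []


def test_single_hot_window_reported_with_max_pi():
    columns = [("A", "A")] * 600
    hot = [("A", "C")] * 9 + [("A", "A")] * 591  # pi = 0.015
    track = sliding_pi(columns + hot, window=600, step=600)
    regions = detect_hotspots(track)
    assert len(regions) == 1
    assert regions[0].max_pi == pytest.approx(0.015)


def test_threshold_is_strict():
    columns = [("A", "C")] * 3 + [("A", "A")] * 497  # pi = 0.006 exactly
    track = sliding_pi(columns, window=500, step=500)
    assert track[0].pi == pytest.approx(0.006)
    assert detect_hotspots(track, threshold=0.006) == []


def test_adjacent_hot_windows_merge():
    hot = [("A", "C")] * 20 + [("A", "A")] * 380
    track = sliding_pi(hot * 3, window=400, step=400)
    regions = detect_hotspots(track)
    assert len(regions) == 1
    assert regions[0].n_windows == 3


# ---------------------------------------------------------------------------
# K2P


def test_k2p_identical_sequences():
    d, P, Q = k2p_distance([("A", "A"), ("C", "C")])
    assert (d, P, Q) == (0.0, 0.0, 0.0)


def test_k2p_closed_form_single_transition():
    columns = [("A", "A")] * 99 + [("A", "G")]
    d, P, Q = k2p_distance(columns)
    assert P == pytest.approx(0.01) and Q == 0.0
    assert d == pytest.approx(-0.5 * math.log(0.98))


def test_k2p_high_divergence_still_finite():
    # P = Q = 0.25: 1 - 2P - Q = 0.25 > 0
    columns = (
        [("A", "G")] * 25 + [("A", "C")] * 25 + [("A", "A")] * 50
    )
    d, P, Q = k2p_distance(columns)
    assert (P, Q) == (0.25, 0.25)
    expected = -0.5 * math.log(0.25) - 0.25 * math.log(0.5)
    assert d == pytest.approx(expected)


def test_k2p_saturation_raises():
    with pytest.raises(SaturationError):
        k2p_distance([("A", "G")] * 10)


@pytest.mark.parametrize("seed", range(5))
def test_k2p_never_below_p_distance(seed):
    rng = np.random.default_rng(seed)
    n, k = 500, int(rng.integers(0, 100))
    bases = rng.choice(list("ACGT"), size=n)
    other = bases.copy()
    idx = rng.choice(n, size=k, replace=False)
    for i in idx:
        other[i] = rng.choice([b for b in "ACGT" if b != bases[i]])
    columns = list(zip(bases, other))
    try:
        d, P, Q = k2p_distance(columns)
    except SaturationError:
        return
    assert d >= P + Q - 1e-12


# ---------------------------------------------------------------------------
# NG86 oracle

_TABLE = unambiguous_dna_by_id[11]
_SENSE = sorted(set(_TABLE.forward_table) - set(_TABLE.stop_codons))


def _aa(codon):
    return "*" if codon in _TABLE.stop_codons else _TABLE.forward_table[codon]


def _oracle_syn_sites(codon):
    total = 0.0
    for pos in range(3):
        syn = sum(
            1
            for b in "ACGT"
            if b != codon[pos]
            and _aa(codon[:pos] + b + codon[pos + 1 :]) == _aa(codon)
            and _aa(codon) != "*"
        )
        total += syn / 3.0
    return total


def _oracle_path_counts(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results, results_all = [], []
    for order in permutations(diff):
        cur, syn, non, bad = c1, 0, 0, False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*" and step < len(order) - 1:
                bad = True
            if _aa(nxt) == _aa(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        results_all.append((syn, non))
        if not bad:
            results.append((syn, non))
    use = results or results_all
    return (
        sum(r[0] for r in use) / len(use),
        sum(r[1] for r in use) / len(use),
    )


def test_ng86_matches_pathway_enumeration_oracle_on_all_codon_pairs():
    """Exhaustive check over all sense-codon pairs (3721 combinations)."""
    checked = 0
    for c1 in _SENSE:
        s1 = _oracle_syn_sites(c1)
        for c2 in _SENSE:
            sd, nd = _oracle_path_counts(c1, c2)
            S = (s1 + _oracle_syn_sites(c2)) / 2.0
            N = 3.0 - S
            ps, pn = sd / S if S else 0.0, nd / N if N else 0.0
            exp_ks = (
                math.inf if 1 - 4 * ps / 3 <= 0 else -0.75 * math.log(1 - 4 * ps / 3)
            )
            exp_ka = (
                math.inf if 1 - 4 * pn / 3 <= 0 else -0.75 * math.log(1 - 4 * pn / 3)
            )
            ka, ks, _ = ng86_kaks([(c1, c2)], on_saturation="inf")
            assert ka == pytest.approx(exp_ka, abs=1e-12), (c1, c2)
            assert ks == pytest.approx(exp_ks, abs=1e-12), (c1, c2)
            checked += 1
    assert checked == len(_SENSE) ** 2 == 3721


def test_ng86_identical_sequences():
    ka, ks, ratio = ng86_kaks([("ATG", "ATG"), ("AAA", "AAA")])
    assert (ka, ks, ratio) == (0.0, 0.0, None)


def test_ng86_synonymous_only_change():
    # Gly GGC -> GGT: third-position change, no amino-acid change
    ka, ks, ratio = ng86_kaks([("GGC", "GGT")], on_saturation="inf")
    assert ka == 0.0
    assert ks > 0
    assert ratio == 0.0


def test_ng86_nonsynonymous_only_change():
    # Phe TTT -> Leu TTA: Ka > 0, Ks = 0, ratio undefined
    ka, ks, ratio = ng86_kaks([("TTT", "TTA")])
    assert ka > 0
    assert ks == 0.0
    assert ratio is None


def test_ng86_saturation_raises_by_default():
    with pytest.raises(SaturationError):
        ng86_kaks([("GGC", "GGT")])


def test_ng86_internal_stop_rejected():
    with pytest.raises(IntegrityError):
        ng86_kaks([("TAA", "TAA"), ("AAA", "AAA")])


def test_strand_invariance_of_pi_and_kaks(cds_pairs):
    """Reverse-complementing both sequences leaves Pi, Ka, Ks unchanged."""
    gene, copy, cds_a, cds_b = next(
        p for p in cds_pairs if p[2] != p[3]
    )
    cols_fwd = list(zip(cds_a, cds_b))
    cols_rev = list(zip(reverse_complement(cds_a), reverse_complement(cds_b)))
    pi_fwd = sliding_pi(cols_fwd, window=len(cols_fwd), step=len(cols_fwd))
    pi_rev = sliding_pi(cols_rev, window=len(cols_rev), step=len(cols_rev))
    assert pi_fwd[0].pi == pi_rev[0].pi
    d_fwd = k2p_distance(cols_fwd)
    d_rev = k2p_distance(cols_rev)
    assert d_fwd[0] == pytest.approx(d_rev[0])
    # Ka/Ks on the reverse strand is computed on the re-oriented frame
    pairs_fwd = [(cds_a[i : i + 3], cds_b[i : i + 3]) for i in range(0, len(cds_a), 3)]
    ra = reverse_complement(cds_a)
    rb = reverse_complement(cds_b)
    pairs_back = [
        (reverse_complement(x), reverse_complement(y))
        for x, y in [(ra[i : i + 3], rb[i : i + 3]) for i in range(0, len(ra), 3)]
    ][::-1]
    assert ng86_kaks(pairs_fwd) == ng86_kaks(pairs_back)


# ---------------------------------------------------------------------------
# selection classes


@pytest.mark.parametrize(
    "ka,ks,expected",
    [
        (0.002, 0.001, "positive"),
        (0.001, 0.001, "neutral"),
        (0.0005, 0.001, "purifying"),
        (0.0, 0.003, "strong_purifying"),
        (0.001, 0.0, "undefined"),
        (0.0, 0.0, "undefined"),
    ],
)
def test_selection_classification(ka, ks, expected):
    assert classify_selection(ka, ks) == expected


def test_selection_rejects_negative_rates():
    with pytest.raises(ValueError):
        classify_selection(-0.1, 0.2)
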