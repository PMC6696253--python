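"""Divergence statistics between two aligned plastomes.

Implements sliding-window nucleotide diversity (for a two-sequence
alignment, Pi per window reduces to the p-distance over valid columns),
divergence-hotspot calling, the Kimura two-parameter distance, and the
Nei-Gojobori (1986) Ka/Ks estimator with fractional site counting and
minimal-pathway averaging, Jukes-Cantor corrected.

Column convention: an aligned column is a ``(baseA, baseB)`` pair, ``"-"``
denoting a gap.  Columns with a gap or an ambiguous base (N) in either
sequence are excluded from both numerator and denominator of every
statistic (pairwise complete deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .errors import IntegrityError, SaturationError

Column = tuple[str, str]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
VALID_BASES = {"A", "C", "G", "T"}

PLASTID_TABLE = 11  # bacterial/plastid code (same codon assignments as standard)


@lru_cache(maxsize=None)
def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate(table=PLASTID_TABLE))


def is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


# ---------------------------------------------------------------------------
# Sliding-window nucleotide diversity


@dataclass
class PiWindow:
    window_start: int  # genome-A coordinates, 0-based half-open
    window_end: int
    valid_sites: int
    differences: int
    partial: bool = False

    @property
    def pi(self) -> float | None:
        if self.valid_sites == 0:
            return None
        return self.differences / self.valid_sites


def sliding_pi(
    columns: Sequence[Column], window: int = 600, step: int = 200
) -> list[PiWindow]:
    """Tile genome-A coordinates with [0,w), [s,s+w), ... windows.

    The final window may be partial (shorter than ``window``); it is kept
    and flagged.  A window without any valid column reports ``pi = None``.
    """
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    # per-A-site difference/validity tracks (insertion columns have no A site)
    valid: list[bool] = []
    diff: list[bool] = []
    for a, b in columns:
        if a == "-":
            continue
        ok = a in VALID_BASES and b in VALID_BASES
        valid.append(ok)
        diff.append(ok and a != b)
    n = len(valid)
    out: list[PiWindow] = []
    for start in range(0, n, step):
        end = min(start + window, n)
        out.append(
            PiWindow(
                window_start=start,
                window_end=end,
                valid_sites=sum(valid[start:end]),
                differences=sum(diff[start:end]),
                partial=end - start < window,
            )
        )
    return out


@dataclass
class HotspotRegion:
    start: int
    end: int
    n_windows: int
    max_pi: float


def detect_hotspots(
    track: Sequence[PiWindow], threshold: float = 0.006
) -> list[HotspotRegion]:
    """Windows with pi strictly above ``threshold``; adjacent ones merged."""
    if not track:
        raise ValueError("empty Pi track")
    regions: list[HotspotRegion] = []
    run: list[PiWindow] = []
    for w in track:
        flagged = w.pi is not None and w.pi > threshold
        if flagged:
            run.append(w)
        elif run:
            regions.append(_close_region(run))
            run = []
    if run:
        regions.append(_close_region(run))
    return regions


def _close_region(run: list[PiWindow]) -> HotspotRegion:
    return HotspotRegion(
        start=run[0].window_start,
        end=run[-1].window_end,
        n_windows=len(run),
        max_pi=max(w.pi for w in run),
    )


# ---------------------------------------------------------------------------
# Kimura two-parameter distance


def k2p_distance(columns: Iterable[Column]) -> tuple[float, float, float]:
    """K2P distance with transition (P) and transversion (Q) proportions.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q), transitions being A<->G and
    C<->T.  Gap/N columns are excluded from the site count.
    """
    valid = transitions = transversions = 0
    for a, b in columns:
        if a not in VALID_BASES or b not in VALID_BASES:
            continue
        valid += 1
        if a != b:
            if is_transition(a, b):
                transitions += 1
            else:
                transversions += 1
    if valid == 0:
        raise IntegrityError("no valid (gap-free, unambiguous) columns")
    P = transitions / valid
    Q = transversions / valid
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P undefined for P={P:.4f}, Q={Q:.4f}")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return d, P, Q


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks


def _synonymous_fraction(codon: str) -> float:
    """Fractional count of synonymous sites in one codon (changes to stop
    codons count as nonsynonymous)."""
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            alt_aa = translate_codon(alt)
            if alt_aa == aa and alt_aa != "*":
                syn += 1
        s += syn / 3.0
    return s


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts over all
    minimal substitution pathways between two codons.

    Pathways passing through a stop codon are discarded; if every pathway
    does, all are kept (the codons themselves are sense codons).
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    kept: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in permutations(positions):
        cur = c1
        syn = non = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = translate_codon(cur), translate_codon(nxt)
            if aa_nxt == "*" and pos != order[-1]:
                through_stop = True
            if aa_cur == aa_nxt:
                syn += 1
            else:
                non += 1
            cur = nxt
        all_paths.append((syn, non))
        if not through_stop:
            kept.append((syn, non))
    paths = kept or all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float, *, on_saturation: str = "raise") -> float:
    w = 1.0 - 4.0 * p / 3.0
    if w <= 0:
        if on_saturation == "inf":
            return math.inf
        raise SaturationError(f"Jukes-Cantor undefined for p={p:.4f}")
    return -0.75 * math.log(w) + 0.0


def ng86_kaks(
    codon_pairs: Sequence[tuple[str, str]], *, on_saturation: str = "raise"
) -> tuple[float, float, float | None]:
    """Nei-Gojobori Ka and Ks over aligned codon pairs.

    Synonymous/nonsynonymous sites are counted fractionally per codon and
    averaged over the two sequences; multi-hit codons are resolved by
    averaging over all minimal substitution pathways; pN and pS receive the
    Jukes-Cantor correction.  Ka/Ks is ``None`` when Ks = 0.
    """
    if not codon_pairs:
        raise IntegrityError("empty codon list")
    s1 = s2 = sd = nd = 0.0
    n_codons = 0
    for i, (c1, c2) in enumerate(codon_pairs):
        if "-" in c1 + c2 or "N" in c1 + c2:
            continue  # pairwise deletion at codon granularity
        last = i == len(codon_pairs) - 1
        for c in (c1, c2):
            if translate_codon(c) == "*" and not last:
                raise IntegrityError(f"internal stop codon {c} at codon {i + 1}")
        n_codons += 1
        s1 += _synonymous_fraction(c1)
        s2 += _synonymous_fraction(c2)
        d_syn, d_non = _pathway_differences(c1, c2)
        sd += d_syn
        nd += d_non
    if n_codons == 0:
        raise IntegrityError("no ungapped codon pairs")
    S = (s1 + s2) / 2.0
    N = 3.0 * n_codons - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps, on_saturation=on_saturation)
    ka = jukes_cantor(pn, on_saturation=on_saturation)
    ratio = None if ks == 0 else ka / ks
    return ka, ks, ratio


def classify_selection(ka: float, ks: float) -> str:
    """Selection class from Ka/Ks: >1 positive, =1 neutral, <1 purifying;
    Ka = 0 with Ks > 0 is very strong purifying; Ks = 0 leaves the ratio
    undefined."""
    if ka < 0 or ks < 0:
        raise ValueError("Ka and Ks must be non-negative")
    if ks == 0:
        return "undefined"
    if ka == 0:
        return "strong_purifying"
    ratio = ka / ks
    if ratio > 1:
        return "positive"
    if ratio == 1:
        return "neutral"
    return "purifying"


# ---------------------------------------------------------------------------
# Per-gene report


@dataclass
class GeneDivergence:
    gene_name: str
    copy_index: int
    k2p: float | None
    P: float
    Q: float
    ka: float | None
    ks: float | None
    ka_ks: float | None
    selection_class: str


def gene_divergence(
    gene_name: str, copy_index: int, columns: Sequence[Column]
) -> GeneDivergence:
    """K2P + NG86 summary for one aligned gene pair (columns in frame)."""
    try:
        d, P, Q = k2p_distance(columns)
    except SaturationError:
        d, P, Q = None, math.nan, math.nan
    codon_pairs = [
        (
            "".join(a for a, _ in columns[i : i + 3]),
            "".join(b for _, b in columns[i : i + 3]),
        )
        for i in range(0, len(columns) - len(columns) % 3, 3)
    ]
    try:
        ka, ks, ratio = ng86_kaks(codon_pairs)
        cls = classify_selection(ka, ks)
    except SaturationError:
        ka = ks = ratio = None
        cls = "undefined"
    return GeneDivergence(gene_name, copy_index, d, P, Q, ka, ks, ratio, cls)
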