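"""Pairwise whole-plastome and per-gene alignment.

Whole genomes are aligned by anchor-and-chain: unique shared k-mers anchor
a monotone chain, and the short inter-anchor segments are closed with a
global dynamic-programming alignment (match +1, mismatch -1, gap -2; N is
mismatch-neutral).  This presumes co-linear inputs — the regime of two
conspecific plastomes differing by point edits and small indels — and
fails loudly otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import CollinearityError

Column = tuple[str, str]

DEFAULT_K = 21
DEFAULT_BAND = 64  # small indels only; kept for API symmetry
MIN_CHAIN_COVERAGE = 0.5


def _make_aligner() -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if "N" in (x, y):
                matrix[x, y] = 0.0
            else:
                matrix[x, y] = 1.0 if x == y else -1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER = _make_aligner()


def global_align(seq_a: str, seq_b: str) -> list[Column]:
    """Full global DP alignment, returned as (baseA|-, baseB|-) columns."""
    if not seq_a and not seq_b:
        return []
    if not seq_a:
        return [("-", b) for b in seq_b]
    if not seq_b:
        return [(a, "-") for a in seq_a]
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    return list(zip(alignment[0], alignment[1]))


def align_gene_pair(cds_a: str, cds_b: str) -> list[Column]:
    """Global alignment of one homologous gene pair.

    With the default scores, equal-length high-identity CDS pairs align
    gap-free (a substitution column scores -1, cheaper than paired gaps).
    """
    if not cds_a or not cds_b:
        raise ValueError("empty coding sequence")
    return global_align(cds_a, cds_b)


def alignment_score(columns: Sequence[Column]) -> float:
    """Score of an alignment under the module's scoring scheme."""
    score = 0.0
    for a, b in columns:
        if "-" in (a, b):
            score -= 2.0
        elif "N" in (a, b):
            score += 0.0
        else:
            score += 1.0 if a == b else -1.0
    return score


@dataclass
class AlignmentMap:
    """Monotone coordinate correspondence between two genomes."""

    columns: list[Column]
    blocks: list[tuple[int, int, int]] = field(default_factory=list)
    # gaps: ((start, end) in the coordinates of the genome holding the
    # insertion, "A" or "B" = which genome the extra bases are inserted in)
    gaps: list[tuple[tuple[int, int], str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.blocks and not self.gaps:
            self.blocks, self.gaps = _blocks_and_gaps(self.columns)

    @property
    def length_a(self) -> int:
        return sum(1 for a, _ in self.columns if a != "-")

    @property
    def length_b(self) -> int:
        return sum(1 for _, b in self.columns if b != "-")

    def map_a_to_b(self, pos_a: int) -> int | None:
        """Genome-B coordinate aligned to genome-A position, if any."""
        for sa, sb, ln in self.blocks:
            if sa <= pos_a < sa + ln:
                return sb + (pos_a - sa)
        return None


def _blocks_and_gaps(
    columns: Sequence[Column],
) -> tuple[list[tuple[int, int, int]], list[tuple[tuple[int, int], str]]]:
    blocks: list[tuple[int, int, int]] = []
    gaps: list[tuple[tuple[int, int], str]] = []
    pos_a = pos_b = 0
    cur: tuple[int, int, int] | None = None  # (startA, startB, length)
    gap_start: tuple[str, int] | None = None  # (which, start)
    for a, b in columns:
        if a != "-" and b != "-":
            if gap_start is not None:
                which, start = gap_start
                end = pos_a if which == "A" else pos_b
                gaps.append(((start, end), which))
                gap_start = None
            if cur is not None and cur[0] + cur[2] == pos_a and cur[1] + cur[2] == pos_b:
                cur = (cur[0], cur[1], cur[2] + 1)
            else:
                if cur is not None:
                    blocks.append(cur)
                cur = (pos_a, pos_b, 1)
            pos_a += 1
            pos_b += 1
        else:
            if cur is not None:
                blocks.append(cur)
                cur = None
            which = "A" if b == "-" else "B"
            start = pos_a if which == "A" else pos_b
            if gap_start is None:
                gap_start = (which, start)
            elif gap_start[0] != which:
                w, s = gap_start
                gaps.append(((s, pos_a if w == "A" else pos_b), w))
                gap_start = (which, start)
            if which == "A":
                pos_a += 1
            else:
                pos_b += 1
    if cur is not None:
        blocks.append(cur)
    if gap_start is not None:
        which, start = gap_start
        end = pos_a if which == "A" else pos_b
        gaps.append(((start, end), which))
    return blocks, gaps


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dupes: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in dupes:
            continue
        if kmer in seen:
            del seen[kmer]
            dupes.add(kmer)
        else:
            seen[kmer] = i
    return seen


def _longest_increasing_chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain strictly increasing in both coordinates.

    Anchors arrive sorted by A position (all A positions distinct, all B
    positions distinct); patience sorting on the B coordinate.
    """
    import bisect

    tails: list[int] = []  # B positions
    tail_idx: list[int] = []
    prev = [-1] * len(anchors)
    for i, (_, b) in enumerate(anchors):
        j = bisect.bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            tail_idx.append(i)
        else:
            tails[j] = b
            tail_idx[j] = i
        prev[i] = tail_idx[j - 1] if j > 0 else -1
    chain: list[tuple[int, int]] = []
    i = tail_idx[-1] if tail_idx else -1
    while i >= 0:
        chain.append(anchors[i])
        i = prev[i]
    chain.reverse()
    return chain


def anchor_align(
    seq_a: str, seq_b: str, k: int = DEFAULT_K, band: int = DEFAULT_BAND
) -> AlignmentMap:
    """Anchor-and-chain alignment of two co-linear genomes.

    Unique shared k-mers are chained by longest strictly-increasing
    subsequence; contiguous same-diagonal anchors collapse into exact
    blocks, and the segments between blocks are closed by global DP.
    A chain covering less than half of either genome raises
    :class:`CollinearityError` (likely a rearrangement or inversion).
    """
    if seq_a == seq_b:
        return AlignmentMap(columns=list(zip(seq_a, seq_b)))
    kmers_a = _unique_kmers(seq_a, k)
    kmers_b = _unique_kmers(seq_b, k)
    anchors = sorted(
        (pos_a, kmers_b[kmer])
        for kmer, pos_a in kmers_a.items()
        if kmer in kmers_b
    )
    chain = _longest_increasing_chain(anchors)
    # drop anchors whose k-mer spans would overlap a predecessor on a
    # different diagonal (keeps the chain consistent at block granularity)
    filtered: list[tuple[int, int]] = []
    for a, b in chain:
        if filtered:
            pa, pb = filtered[-1]
            same_diag = a - b == pa - pb
            if not same_diag and (a < pa + k or b < pb + k):
                continue
        filtered.append((a, b))
    # merge into maximal exact runs
    runs: list[tuple[int, int, int]] = []  # (startA, startB, length)
    for a, b in filtered:
        if runs:
            sa, sb, ln = runs[-1]
            if a - b == sa - sb and a <= sa + ln:
                runs[-1] = (sa, sb, a + k - sa)
                continue
        runs.append((a, b, k))
    covered_a = sum(ln for _, _, ln in runs)
    covered_b = covered_a
    if (
        not runs
        or covered_a < MIN_CHAIN_COVERAGE * len(seq_a)
        or covered_b < MIN_CHAIN_COVERAGE * len(seq_b)
    ):
        raise CollinearityError(
            "anchor chain covers less than half of the genomes; "
            "inputs do not look co-linear"
        )
    # stitch: exact runs + DP-closed inter-run segments
    columns: list[Column] = []
    prev_a = prev_b = 0
    for sa, sb, ln in runs:
        columns.extend(global_align(seq_a[prev_a:sa], seq_b[prev_b:sb]))
        columns.extend(zip(seq_a[sa : sa + ln], seq_b[sb : sb + ln]))
        prev_a, prev_b = sa + ln, sb + ln
    columns.extend(global_align(seq_a[prev_a:], seq_b[prev_b:]))
    return AlignmentMap(columns=columns)
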