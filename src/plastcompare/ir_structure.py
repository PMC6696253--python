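"""Quadripartite partition detection and IR-junction gene offsets.

A plastome's two inverted repeats (IRa, IRb) are located as the longest
pair of disjoint segments where one is exactly the reverse complement of
the other, extended maximally (circularly).  The longer of the two
inter-IR arcs is the LSC, the shorter the SSC.  Junction names follow the
standard convention: JLB (LSC/IRb), JSB (SSC/IRb), JSA (SSC/IRa),
JLA (LSC/IRa).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import StructureError
from .genome_io import AnnotationSet, GenomeRecord, reverse_complement

_SEED_K = 25


@dataclass
class Region:
    """[start, end) on the linearized genome; end may exceed the genome
    length for an origin-wrapping region (interpret modulo length)."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class QuadripartitePartition:
    genome_id: str
    genome_length: int
    lsc: Region
    irb: Region
    ssc: Region
    ira: Region

    @property
    def junctions(self) -> dict[str, int]:
        n = self.genome_length
        return {
            "JLB": self.irb.start % n,
            "JSB": self.irb.end % n,
            "JSA": self.ira.start % n,
            "JLA": self.ira.end % n,
        }

    def region_of(self, pos: int) -> str:
        pos %= self.genome_length
        for name in ("lsc", "irb", "ssc", "ira"):
            region: Region = getattr(self, name)
            s, e = region.start, region.end
            if s <= pos < e or s <= pos + self.genome_length < e:
                return name.upper().replace("IRB", "IRb").replace("IRA", "IRa")
        raise AssertionError("partition does not tile the genome")


def find_inverted_repeats(
    genome: GenomeRecord, min_len: int = 1000
) -> QuadripartitePartition:
    """Locate the IR pair and derive the quadripartite partition.

    Seed-and-extend against the reverse complement: every exact seed match
    between the genome and its reverse complement is extended maximally
    (with circular wrap-around), and the longest disjoint pair is kept.
    The segment with the smaller start coordinate is IRb, matching the
    conventional LSC-first linearization.
    """
    seq = genome.sequence
    n = len(seq)
    if n < 2 * min_len:
        raise StructureError(f"genome too short for IRs of >= {min_len} bp")
    rc = reverse_complement(seq)
    # index seeds of the reverse complement
    k = min(_SEED_K, min_len)
    rc_index: dict[str, list[int]] = {}
    for i in range(0, n - k + 1, k):
        rc_index.setdefault(rc[i : i + k], []).append(i)
    best: tuple[int, int, int] | None = None  # (length, start1, start2)
    seen_diagonals: set[int] = set()
    for i in range(n - k + 1):
        for j in rc_index.get(seq[i : i + k], ()):
            # match: seq[i:i+k] == rc[j:j+k]  <=>  revcomp of seq segment
            # starting at n-j-k
            diag = (i - j) % n
            if diag in seen_diagonals:
                continue
            seen_diagonals.add(diag)
            s1, s2, length = _extend_circular(seq, rc, i, j)
            other = n - (s2 + length)  # genome coordinate of the partner
            if length >= min_len and _disjoint(s1, other, length, n):
                if best is None or length > best[0]:
                    best = (length, s1 % n, other % n)
    if best is None:
        raise StructureError(f"no inverted repeat of >= {min_len} bp found")
    length, a, b = best
    first, second = sorted((a, b))
    irb = Region(first, first + length)
    ira = Region(second, second + length)
    gap1 = Region(irb.end, ira.start)  # between the two IR copies
    gap2 = Region(ira.end, irb.start + n)  # the arc wrapping the origin
    if gap2.length >= gap1.length:
        lsc, ssc = gap2, gap1
    else:
        # the longer arc lies between the copies: relabel so that IRb is
        # the copy that follows the LSC in circular order
        lsc, ssc = gap1, gap2
        irb, ira = ira, Region(irb.start + n, irb.end + n)
    lsc, irb, ssc, ira = (
        Region(r.start - n, r.end - n) if r.start >= n else r
        for r in (lsc, irb, ssc, ira)
    )
    return QuadripartitePartition(
        genome_id=genome.id,
        genome_length=n,
        lsc=lsc,
        irb=irb,
        ssc=ssc,
        ira=ira,
    )


def _extend_circular(seq: str, rc: str, i: int, j: int) -> tuple[int, int, int]:
    """Maximally extend an exact match seq[i:]==rc[j:] in both directions,
    wrapping circularly; returns (start_seq, start_rc, length)."""
    n = len(seq)
    left = 0
    while left < n and seq[(i - left - 1) % n] == rc[(j - left - 1) % n]:
        left += 1
    right = 0
    while right < n and seq[(i + right) % n] == rc[(j + right) % n]:
        right += 1
    length = min(left + right, n)
    return i - left, j - left, length


def _disjoint(start1: int, start2: int, length: int, n: int) -> bool:
    s1, s2 = sorted((start1 % n, start2 % n))
    return s1 + length <= s2 and s2 + length <= s1 + n


# ---------------------------------------------------------------------------
# Junction offsets


@dataclass
class JunctionGene:
    junction: str  # JLB | JSB | JSA | JLA
    junction_position: int  # 0-based internal coordinate
    gene_name: str
    copy_index: int
    feature_type: str
    region: str  # region holding (most of) the gene
    spans_junction: bool
    distance: int  # bp from nearest gene end to the junction (0 if spanning)
    bp_upstream: int  # bp on the lower-coordinate side (when spanning)
    bp_downstream: int  # bp on the higher-coordinate side (when spanning)


def junction_offsets(
    partition: QuadripartitePartition,
    annot: AnnotationSet,
    flank: int = 1000,
) -> list[JunctionGene]:
    """Genes within ``flank`` bp of each junction, with contraction gaps
    (gene ends short of the junction) and expansion overlaps (gene spans
    the junction, reported as bp in each flanking region)."""
    n = partition.genome_length
    out: list[JunctionGene] = []
    for jname, jpos in partition.junctions.items():
        for feat in annot.features:
            start, end = feat.span(n)
            # evaluate the junction in the coordinate frame nearest the gene
            jcands = [jpos, jpos + n, jpos - n]
            j = min(jcands, key=lambda x: _interval_distance(start, end, x))
            if start < j < end:
                spans, dist = True, 0
                up, down = j - start, end - j
            else:
                spans = False
                dist = min(abs(start - j), abs(end - j))
                up = down = 0
                if dist > flank:
                    continue
            if spans or dist <= flank:
                mid = (start + end) // 2
                out.append(
                    JunctionGene(
                        junction=jname,
                        junction_position=jpos,
                        gene_name=feat.gene_name,
                        copy_index=feat.copy_index,
                        feature_type=feat.feature_type,
                        region=partition.region_of(mid),
                        spans_junction=spans,
                        distance=dist,
                        bp_upstream=up,
                        bp_downstream=down,
                    )
                )
    return out


def _interval_distance(start: int, end: int, pos: int) -> int:
    if start <= pos < end:
        return 0
    return min(abs(start - pos), abs(end - pos))
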