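"""Reading, writing and slicing annotated plastomes.

File boundaries use the conventions of the formats themselves (FASTA; GFF3
with 1-based inclusive coordinates).  Internally every coordinate is 0-based
half-open.  Sequences are stored uppercase over {A, C, G, T, N}: ``U`` is
mapped to ``T`` and any other IUPAC ambiguity code collapses to ``N``;
characters outside the IUPAC nucleotide alphabet are rejected.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, FormatError, IntegrityError

IUPAC_CODES = set("ACGTUNRYSWKMBDHV")
_AMBIGUOUS = str.maketrans({c: "N" for c in "RYSWKMBDHV"})

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def normalize_sequence(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T, collapse ambiguity codes to N; reject the rest."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - IUPAC_CODES
    if bad:
        raise FormatError(
            f"{context}: non-nucleotide characters {sorted(bad)!r}"
        )
    return seq.translate(_AMBIGUOUS)


@dataclass
class GenomeRecord:
    """One plastome sequence (circular by default)."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence, context=self.id)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Slice [start, end); ``end <= start`` wraps the origin on circles."""
        if 0 <= start <= end <= self.length:
            return self.sequence[start:end]
        if not self.circular:
            raise CoordinateError(
                f"{self.id}: [{start}, {end}) outside linear genome of "
                f"length {self.length}"
            )
        start %= self.length
        end %= self.length
        if start < end:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]


@dataclass
class GeneFeature:
    """A strand-aware, possibly multi-exon gene model.

    ``exons`` are 0-based half-open genome intervals in genomic order.  An
    exon whose end is <= its start denotes an origin-spanning exon on a
    circular genome.
    """

    gene_name: str
    feature_type: str  # CDS | tRNA | rRNA
    strand: str  # '+' | '-'
    exons: list[tuple[int, int]]
    trans_spliced: bool = False
    copy_index: int = 0
    partial: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(
                f"{self.gene_name}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise CoordinateError(f"{self.gene_name}: no exons")

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene_name, self.copy_index)

    def span(self, genome_length: int | None = None) -> tuple[int, int]:
        """Smallest [start, end) interval covering all exons (no wrap)."""
        starts = [s for s, _ in self.exons]
        ends = [e if e > s else e + (genome_length or 0) for s, e in self.exons]
        return min(starts), max(ends)


@dataclass
class AnnotationSet:
    genome_id: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [f.key for f in self.features]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise IntegrityError(f"duplicate gene/copy keys: {dupes}")

    def of_type(self, feature_type: str) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_type == feature_type]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    records = [
        GenomeRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# GFF3


def read_annotations(
    path: str | Path,
    dialect: str = "gff3",
    *,
    genome_length: int | None = None,
    circular: bool = True,
) -> AnnotationSet:
    """Read gene models from GFF3 (CDS exons grouped via Parent).

    Coordinates are converted from the file's 1-based inclusive convention
    to internal 0-based half-open.  ``genome_length``, when given, is used
    to bounds-check exons (on linear records an out-of-bounds exon is a
    :class:`CoordinateError`).
    """
    if dialect != "gff3":
        raise FormatError(f"unsupported annotation dialect: {dialect!r}")
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    genome_id = ""
    # CDS segments grouped by parent gene feature
    by_parent: dict[str, list[gffutils.Feature]] = {}
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", [cds.id or "?"])[0]
        by_parent.setdefault(parent, []).append(cds)
        genome_id = cds.seqid
    for parent_id, segments in by_parent.items():
        segments.sort(key=lambda f: f.start)
        strand = segments[0].strand
        attrs = segments[0].attributes
        try:
            parent_attrs = db[parent_id].attributes
        except gffutils.FeatureNotFoundError:
            parent_attrs = attrs
        name = _first(parent_attrs, attrs, keys=("gene", "Name"), default=parent_id)
        features.append(
            GeneFeature(
                gene_name=name,
                feature_type="CDS",
                strand=_check_strand(strand, name),
                exons=[(f.start - 1, f.end) for f in segments],
                trans_spliced=_flag(parent_attrs, attrs, "trans_spliced"),
                copy_index=int(
                    _first(parent_attrs, attrs, keys=("copy_index",), default="0")
                ),
                partial=_flag(parent_attrs, attrs, "partial"),
            )
        )
    for ftype in ("tRNA", "rRNA"):
        for f in db.features_of_type(ftype):
            name = _first(f.attributes, f.attributes, keys=("gene", "Name"), default=f.id)
            features.append(
                GeneFeature(
                    gene_name=name,
                    feature_type=ftype,
                    strand=_check_strand(f.strand, name),
                    exons=[(f.start - 1, f.end)],
                    copy_index=int(f.attributes.get("copy_index", ["0"])[0]),
                )
            )
            genome_id = f.seqid
    if genome_length is not None and not circular:
        for feat in features:
            for s, e in feat.exons:
                if s < 0 or e > genome_length:
                    raise CoordinateError(
                        f"{feat.gene_name}: exon ({s + 1}..{e}) outside "
                        f"genome of length {genome_length}"
                    )
    return AnnotationSet(genome_id=genome_id, features=features)


def _check_strand(strand: str, name: str) -> str:
    if strand not in "+-":
        raise FormatError(f"{name}: unknown strand symbol {strand!r}")
    return strand


def _first(primary, secondary, *, keys, default):
    for attrs in (primary, secondary):
        for key in keys:
            if key in attrs:
                return attrs[key][0]
    return default


def _flag(primary, secondary, key) -> bool:
    return _first(primary, secondary, keys=(key,), default="false").lower() == "true"


def write_annotations(annot: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet as GFF3 (gene parents + CDS/tRNA/rRNA lines)."""
    lines = ["##gff-version 3"]
    for feat in annot.features:
        gid = f"{feat.gene_name}.{feat.copy_index}"
        start = min(s for s, _ in feat.exons) + 1
        end = max(e for _, e in feat.exons)
        attrs = f"ID=gene-{gid};gene={feat.gene_name};copy_index={feat.copy_index}"
        if feat.trans_spliced:
            attrs += ";trans_spliced=true"
        if feat.partial:
            attrs += ";partial=true"
        lines.append(
            "\t".join(
                [annot.genome_id, "plastcompare", "gene", str(start), str(end),
                 ".", feat.strand, ".", attrs]
            )
        )
        for i, (s, e) in enumerate(feat.exons):
            lines.append(
                "\t".join(
                    [annot.genome_id, "plastcompare", feat.feature_type,
                     str(s + 1), str(e), ".", feat.strand,
                     "0" if feat.feature_type == "CDS" else ".",
                     f"ID=cds-{gid}.{i};Parent=gene-{gid}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CDS extraction


def extract_cds(
    genome: GenomeRecord,
    annot: AnnotationSet,
    skip_trans_spliced: bool = True,
) -> list[tuple[str, int, str]]:
    """Concatenate, splice and strand-correct every annotated CDS.

    Returns ``(gene_name, copy_index, coding_sequence)`` triples in
    annotation order.  Minus-strand features are reverse-complemented after
    exon concatenation in genomic order (exons of one plastid gene are
    co-linear).  Trans-spliced genes (rps12-style) are omitted when
    ``skip_trans_spliced`` is true.
    """
    out: list[tuple[str, int, str]] = []
    for feat in annot.of_type("CDS"):
        if feat.trans_spliced and skip_trans_spliced:
            continue
        parts = [genome.fetch(s, e) for s, e in feat.exons]
        cds = "".join(parts)
        if feat.strand == "-":
            cds = reverse_complement(cds)
        if len(cds) % 3 and not feat.partial:
            raise IntegrityError(
                f"{feat.gene_name}: CDS length {len(cds)} not a multiple of 3"
            )
        out.append((feat.gene_name, feat.copy_index, cds))
    return out


def annotations_from_string(gff_text: str, **kwargs) -> AnnotationSet:
    """Convenience for tests: parse GFF3 from an in-memory string."""
    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
        fh.write(gff_text)
        name = fh.name
    try:
        return read_annotations(name, **kwargs)
    finally:
        Path(name).unlink(missing_ok=True)
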