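"""Synthetic plastome-pair generator with a ground-truth table.

Builds a quadripartite genome A as LSC + IRb + SSC + revcomp(IRb), plants
genes (multi-exon, strand-diverse, one IR-duplicated), SSRs (including
compound formations) and boundary genes at configurable IR-junction
offsets, then derives genome B by applying an explicit SNP and indel
specification.  Everything planted is recorded in a :class:`TruthTable`
with coordinates resolvable in both genomes, so every downstream stage of
the pipeline can be tested against known truth without external data.

The default configuration is a desk-scale (14 kb) genome pair whose 24
planted coding SNPs mirror the class mix observed between the two
sugarcane ancestor plastomes: 12 transitions (8 A<->G, 4 C<->T) and 12
transversions, 18 nonsynonymous and 6 synonymous, including a pair of
substitutions duplicated with the IR gene copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import SpecError
from .genome_io import (
    AnnotationSet,
    GeneFeature,
    GenomeRecord,
    reverse_complement,
    write_annotations,
    write_fasta,
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

# thresholds union used to reject accidental repeats in compound gaps
_GAP_CHECK_THRESHOLDS = {1: 8, 2: 5, 3: 3, 4: 3, 5: 2, 6: 2}


@dataclass(frozen=True)
class SnpSpec:
    gene: str
    codon_position: int  # 1, 2 or 3
    substitution_class: str  # transition | transversion
    coding_effect: str  # synonymous | nonsynonymous
    ts_subtype: str | None = None  # "A<->G" | "C<->T" (transitions only)


@dataclass(frozen=True)
class IndelSpec:
    region: str  # LSC | SSC
    length: int  # >0: insertion in genome B; <0: deletion from genome B


@dataclass(frozen=True)
class SsrPlantSpec:
    motif: str
    repeat_count: int
    region: str = "LSC"
    compound_gap: int | str | None = None  # gap length or literal gap string


def _default_snp_spec() -> list[SnpSpec]:
    ts, tv = "transition", "transversion"
    non, syn = "nonsynonymous", "synonymous"
    return [
        # A<->G transitions, nonsynonymous
        SnpSpec("gene01", 1, ts, non, "A<->G"),
        SnpSpec("gene02", 2, ts, non, "A<->G"),
        SnpSpec("gene03", 1, ts, non, "A<->G"),
        SnpSpec("gene04", 2, ts, non, "A<->G"),
        SnpSpec("gene05", 1, ts, non, "A<->G"),
        # synonymous transitions
        SnpSpec("gene06", 3, ts, syn, "A<->G"),
        SnpSpec("gene07", 3, ts, syn, "C<->T"),
        SnpSpec("gene08", 3, ts, syn, "C<->T"),
        SnpSpec("geneSC", 3, ts, syn, "C<->T"),
        SnpSpec("jlaGene", 3, ts, syn, "C<->T"),
        # transversions, nonsynonymous
        SnpSpec("gene01", 2, tv, non),
        SnpSpec("gene02", 1, tv, non),
        SnpSpec("gene03", 2, tv, non),
        SnpSpec("gene04", 1, tv, non),
        SnpSpec("gene05", 2, tv, non),
        SnpSpec("gene09", 1, tv, non),
        SnpSpec("gene10", 2, tv, non),
        SnpSpec("jlbGene", 1, tv, non),
        SnpSpec("jsaGene", 2, tv, non),
        # synonymous transversion
        SnpSpec("gene06", 3, tv, syn),
        # IR-duplicated gene: each change appears once per copy
        SnpSpec("geneIR", 2, ts, non, "A<->G"),
        SnpSpec("geneIR", 3, tv, non),
    ]


def _default_ssr_spec() -> list[SsrPlantSpec]:
    return [
        SsrPlantSpec("A", 13),
        SsrPlantSpec("T", 12),
        SsrPlantSpec("G", 10),
        SsrPlantSpec("AT", 6),
        SsrPlantSpec("AAT", 5),
        SsrPlantSpec("T", 10, compound_gap="CTCTCCTA"),  # 28 bp span
        SsrPlantSpec("A", 10, compound_gap=45),  # 65 bp span
    ]


@dataclass
class SyntheticConfig:
    region_lengths: tuple[int, int, int] = (8400, 2100, 1400)  # LSC, IR, SSC
    n_genes: int = 12  # interior genes: n-2 in LSC, 1 in IRb, 1 in SSC
    snp_spec: list[SnpSpec] = field(default_factory=_default_snp_spec)
    indel_spec: list[IndelSpec] = field(
        default_factory=lambda: [IndelSpec("LSC", 7), IndelSpec("LSC", -5)]
    )
    ssr_spec: list[SsrPlantSpec] = field(default_factory=_default_ssr_spec)
    # junction -> offset in bp: positive = gene extends past the junction
    # (expansion), negative = gene falls short of it (contraction)
    junction_gene_spec: dict[str, int] = field(
        default_factory=lambda: {"JLB": -35, "JSB": 29, "JSA": -153, "JLA": -90}
    )
    seed: int = 0

    @property
    def total_length(self) -> int:
        lsc, ir, ssc = self.region_lengths
        return lsc + 2 * ir + ssc


def full_scale_config(seed: int = 0) -> SyntheticConfig:
    """A ~140 kb configuration with the same planted truth."""
    return SyntheticConfig(region_lengths=(84000, 21000, 14000), seed=seed)


# ---------------------------------------------------------------------------
# Truth records


@dataclass
class TruthSnp:
    gene: str
    copy_index: int
    gene_position: int  # 1-based on the spliced coding sequence
    ref_base: str
    alt_base: str
    ref_codon: str
    alt_codon: str
    substitution_class: str
    ts_subtype: str
    coding_effect: str
    genome_a_position: int  # 0-based genome-A coordinate


@dataclass
class TruthIndel:
    region: str
    length: int
    genome_a_position: int


@dataclass
class TruthSsr:
    motif: str
    repeats: int
    start_a: int  # 1-based inclusive, genome A
    end_a: int
    start_b: int
    end_b: int
    compound_id: str | None


@dataclass
class TruthJunction:
    junction: str
    gene: str
    offset: int  # positive = expansion past the junction


@dataclass
class TruthTable:
    snps: list[TruthSnp]
    indels: list[TruthIndel]
    ssrs: list[TruthSsr]
    partition_a: dict[str, tuple[int, int]]  # region -> (start, end) 0-based
    partition_b: dict[str, tuple[int, int]]
    junctions: list[TruthJunction]


# ---------------------------------------------------------------------------
# helpers


def _random_background(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _translate(codon: str) -> str:
    from .divergence import translate_codon

    return translate_codon(codon)


def plant_ssrs(
    sequence: str,
    ssr_spec: list[tuple[str, int, int] | tuple[str, int, int, int | str | None]],
    rng: np.random.Generator | None = None,
) -> tuple[str, list[dict]]:
    """Stamp perfect SSR runs into ``sequence`` at explicit positions.

    Each spec entry is ``(motif, repeat_count, position)`` with an optional
    fourth element giving a compound gap (length or literal string) after
    which the run is repeated.  Positions are 0-based; the planted span is
    flanked by guard bases so the run cannot extend by chance.  Returns the
    modified sequence and one coordinate dict per planted run.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    seq = list(sequence)
    planted: list[dict] = []
    used: list[tuple[int, int]] = []
    for entry in ssr_spec:
        motif, count, pos = entry[0], entry[1], entry[2]
        gap = entry[3] if len(entry) > 3 else None
        runs = [(motif, count)]
        gap_seq = ""
        if gap is not None:
            gap_seq = gap if isinstance(gap, str) else _safe_gap(rng, motif, gap)
            runs.append((motif, count))
        text = (motif * count) + gap_seq + (motif * count if gap is not None else "")
        start, end = pos, pos + len(text)
        if end + 1 > len(seq) or pos < 1:
            raise SpecError(f"SSR {motif}x{count} at {pos} outside sequence")
        for s, e in used:
            if start - 1 <= e and s <= end:  # include guard positions
                raise SpecError(f"SSR plant at {pos} overlaps a previous plant")
        used.append((start - 1, end))
        seq[start:end] = list(text)
        # guard bases: break any accidental run extension at the flanks
        seq[start - 1] = _guard_base(motif, first=True)
        if end < len(seq):
            seq[end] = _guard_base(motif, first=False)
        offset = 0
        cid = "C" if gap is not None else None
        for m, c in runs:
            planted.append(
                {
                    "motif": m,
                    "repeats": c,
                    "start": start + offset,
                    "end": start + offset + len(m) * c,  # half-open
                    "compound": cid,
                }
            )
            offset += len(m) * c + len(gap_seq)
    return "".join(seq), planted


def _guard_base(motif: str, first: bool) -> str:
    # any base different from the adjacent motif base breaks the run
    adjacent = motif[-1] if first else motif[0]
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[adjacent]


def _safe_gap(rng: np.random.Generator, motif: str, length: int) -> str:
    """Random spacer that neither contains an SSR nor extends the run."""
    from .ssr import SsrPreset, find_ssrs

    preset = SsrPreset("check", _GAP_CHECK_THRESHOLDS)
    for _ in range(200):
        gap = "".join(rng.choice(list("ACGT"), size=length))
        if gap[0] == motif[-1] or gap[-1] == motif[0]:
            continue
        probe = motif * 2 + gap + motif * 2
        if len(find_ssrs(probe, preset)) == 0:
            return gap
    raise SpecError(f"could not build a repeat-free gap of {length} bp")


# ---------------------------------------------------------------------------
# generator


class _Layout:
    """Planned gene and SSR placements for one synthetic genome."""

    def __init__(self, config: SyntheticConfig):
        lsc, ir, ssc = config.region_lengths
        self.lsc_len, self.ir_len, self.ssc_len = lsc, ir, ssc
        self.jlb = lsc
        self.jsb = lsc + ir
        self.jsa = lsc + ir + ssc
        self.jla = config.total_length  # == 0 mod genome length
        self.core_len = lsc + ir + ssc


def generate_pair(
    config: SyntheticConfig | None = None,
) -> tuple[GenomeRecord, GenomeRecord, AnnotationSet, AnnotationSet, TruthTable]:
    """Generate a synthetic plastome pair plus annotations and truth."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    lay = _Layout(config)
    scale = lay.lsc_len / 8400.0
    if min(config.region_lengths) < 600:
        raise SpecError("regions must be at least 600 bp")

    core = _random_background(rng, lay.core_len)
    features: list[GeneFeature] = []
    junction_truth: list[TruthJunction] = []

    def stamp(start: int, cds: str, name: str, strand: str,
              intron: int | None = None) -> None:
        """Write a CDS (optionally split in two exons) into the core."""
        if strand == "-":
            text = reverse_complement(cds)
        else:
            text = cds
        if intron is None:
            exons = [(start, start + len(cds))]
            core[start : start + len(cds)] = list(text)
        else:
            half = (len(cds) // 6) * 3  # first exon length (in-frame split)
            intron_seq = "".join(rng.choice(list("ACGT"), size=intron))
            # intron must not begin/end looking like part of the CDS; for
            # alignment purposes content is irrelevant
            block = text[:half] + intron_seq + text[half:]
            exons = [(start, start + half),
                     (start + half + intron, start + len(cds) + intron)]
            if strand == "-":
                # exon lengths mirror: genomic-order exons for '-' strand
                first = len(cds) - half
                exons = [(start, start + first),
                         (start + first + intron, start + len(cds) + intron)]
                block = text[:first] + intron_seq + text[first:]
            core[start : start + len(block)] = list(block)
        features.append(
            GeneFeature(gene_name=name, feature_type="CDS", strand=strand,
                        exons=exons)
        )

    # --- junction genes -----------------------------------------------------
    joff = config.junction_gene_spec
    if "JLA" in joff:
        off = joff["JLA"]
        if off > 0:
            raise SpecError("JLA expansion into the derived IRa is unsupported")
        start = -off  # gene begins |off| bp after the origin-side junction
        stamp(start, _random_cds(rng, 140), "jlaGene", "-")
        junction_truth.append(TruthJunction("JLA", "jlaGene", off))
    if "JLB" in joff:
        off = joff["JLB"]
        length = 279
        end = lay.jlb + off
        if off > 60:
            raise SpecError("JLB expansion beyond 60 bp collides with the IR gene")
        stamp(end - length, _random_cds(rng, length // 3), "jlbGene", "+")
        junction_truth.append(TruthJunction("JLB", "jlbGene", off))
    if "JSB" in joff:
        off = joff["JSB"]
        length = 600
        start = lay.jsb - off
        stamp(start, _random_cds(rng, length // 3), "jsbGene", "+")
        junction_truth.append(TruthJunction("JSB", "jsbGene", off))
    if "JSA" in joff:
        off = joff["JSA"]
        if off > 0:
            raise SpecError("JSA expansion into the derived IRa is unsupported")
        length = 270
        end = lay.jsa + off
        stamp(end - length, _random_cds(rng, length // 3), "jsaGene", "-")
        junction_truth.append(TruthJunction("JSA", "jsaGene", off))

    # --- interior genes -----------------------------------------------------
    n_lsc = max(config.n_genes - 2, 1)
    slot = int(450 * max(scale, 1.0))
    start0 = int(700 * max(scale, 1.0))
    for i in range(n_lsc):
        name = f"gene{i + 1:02d}"
        strand = "-" if i in (1, 4) else "+"
        intron = 72 if i == 2 else None
        n_codons = 100
        start = start0 + i * slot
        if start + n_codons * 3 + (intron or 0) > lay.jlb - 400 - int(
            2200 * max(scale, 1.0)
        ):
            raise SpecError("LSC too small for the requested gene count")
        stamp(start, _random_cds(rng, n_codons), name, strand, intron=intron)
    # IR gene (duplicated with the IRa copy)
    ir_start = lay.jlb + 400
    ir_cds = _random_cds(rng, 100)
    stamp(ir_start, ir_cds, "geneIR", "+")
    # SSC interior gene
    sc_start = lay.jsb + (lay.jsb and 0) + (lay.ssc_len // 2) - 60 + lay.jlb + lay.ir_len - lay.jsb
    sc_start = lay.jsb + lay.ssc_len // 2 - 60
    stamp(sc_start, _random_cds(rng, 40), "geneSC", "+")

    # --- planted SSRs -------------------------------------------------------
    ssr_zone = lay.jlb - int(3000 * max(scale, 1.0))
    specs_with_pos = []
    cursor = ssr_zone
    for s in config.ssr_spec:
        if s.region != "LSC":
            base = lay.jsb + 40  # just inside the SSC, before interior gene
        else:
            base = cursor
        specs_with_pos.append((s.motif, s.repeat_count, base, s.compound_gap))
        span = len(s.motif) * s.repeat_count
        if s.compound_gap is not None:
            gap_len = (
                len(s.compound_gap)
                if isinstance(s.compound_gap, str)
                else s.compound_gap
            )
            span = span * 2 + gap_len
        if s.region == "LSC":
            # spacing > the compound-joining gap, so separately planted
            # SSRs are not merged into spurious compounds
            cursor += span + 130
    core_str, planted_ssrs = plant_ssrs("".join(core), specs_with_pos, rng)
    core = list(core_str)

    # --- anti-extension guards at the designed IR boundaries ---------------
    _fix_boundary(core, lay.lsc_len - 1, 0, features, lay)
    _fix_boundary(core, lay.jsa - 1, lay.jsb, features, lay)

    # --- assemble genome A --------------------------------------------------
    irb_slice = core[lay.jlb : lay.jsb]
    genome_a_seq = "".join(core) + reverse_complement("".join(irb_slice))
    n_a = len(genome_a_seq)
    # annotate the IRa copy of the IR gene
    ira_copy = _mirror_feature(features, "geneIR", lay, n_a)
    annot_a_features = [replace(f) for f in features] + [ira_copy]
    genome_a = GenomeRecord(id="synthA", sequence=genome_a_seq)
    annot_a = AnnotationSet(genome_id="synthA", features=annot_a_features)

    # --- plant SNPs into genome B's core ------------------------------------
    core_b = list(core)
    truth_snps: list[TruthSnp] = []
    used_sites: set[tuple[str, int]] = set()
    by_name = {f.gene_name: f for f in features}
    for spec in config.snp_spec:
        feat = by_name.get(spec.gene)
        if feat is None:
            raise SpecError(f"SNP spec names unknown gene {spec.gene!r}")
        truth_snps.extend(
            _plant_snp(core, core_b, feat, spec, rng, used_sites, lay, n_a)
        )

    # --- indels --------------------------------------------------------------
    truth_indels: list[TruthIndel] = []
    indel_positions = _indel_sites(config, lay, features, planted_ssrs)
    edits: list[tuple[int, int]] = []  # (A-coordinate, signed length)
    for spec, pos in zip(config.indel_spec, indel_positions):
        edits.append((pos, spec.length))
        truth_indels.append(TruthIndel(spec.region, spec.length, pos))
    for pos, length in sorted(edits, reverse=True):
        if length > 0:
            core_b[pos:pos] = list(rng.choice(list("ACGT"), size=length))
        else:
            del core_b[pos : pos - length]

    def shift(coord: int) -> int:
        return coord + sum(l for p, l in edits if p < coord)

    irb_b = core_b[shift(lay.jlb) : shift(lay.jsb)]
    genome_b_seq = "".join(core_b) + reverse_complement("".join(irb_b))
    n_b = len(genome_b_seq)
    genome_b = GenomeRecord(id="synthB", sequence=genome_b_seq)

    feats_b = [
        replace(
            f,
            exons=[(shift(s), shift(e)) for s, e in f.exons],
        )
        for f in features
    ]
    lay_b_jlb = shift(lay.jlb)
    annot_b = AnnotationSet(
        genome_id="synthB",
        features=feats_b
        + [_mirror_feature(feats_b, "geneIR", None, n_b, jlb=lay_b_jlb,
                           ir_len=lay.ir_len, jsa=shift(lay.jsa))],
    )

    # duplicate truth SNPs for the IRa copy of the IR gene
    truth_snps = _expand_ir_snps(truth_snps, by_name.get("geneIR"), lay, n_a)

    truth = TruthTable(
        snps=truth_snps,
        indels=truth_indels,
        ssrs=[
            TruthSsr(
                motif=p["motif"],
                repeats=p["repeats"],
                start_a=p["start"] + 1,
                end_a=p["end"],
                start_b=shift(p["start"]) + 1,
                end_b=shift(p["end"] - 1) + 1,
                compound_id=p["compound"],
            )
            for p in planted_ssrs
        ],
        partition_a={
            "LSC": (0, lay.jlb),
            "IRb": (lay.jlb, lay.jsb),
            "SSC": (lay.jsb, lay.jsa),
            "IRa": (lay.jsa, n_a),
        },
        partition_b={
            "LSC": (0, shift(lay.jlb)),
            "IRb": (shift(lay.jlb), shift(lay.jsb)),
            "SSC": (shift(lay.jsb), shift(lay.jsa)),
            "IRa": (shift(lay.jsa), n_b),
        },
        junctions=junction_truth,
    )
    return genome_a, genome_b, annot_a, annot_b, truth


def _fix_boundary(core: list[str], left: int, right: int,
                  features: list[GeneFeature], lay: _Layout) -> None:
    """Break chance reverse-complement identity just outside the designed
    IR boundaries so the detected IR cannot extend past them."""
    spans = [f.span(lay.core_len) for f in features]

    def in_gene(pos: int) -> bool:
        return any(s <= pos < e for s, e in spans)

    if core[left] == COMPLEMENT[core[right]]:
        if not in_gene(left):
            core[left] = core[right]
        elif not in_gene(right):
            core[right] = core[left]


def _mirror_feature(features: list[GeneFeature], name: str, lay, n: int,
                    jlb: int | None = None, ir_len: int | None = None,
                    jsa: int | None = None) -> GeneFeature:
    """Annotation of the IRa copy of an IRb-resident gene."""
    src = next(f for f in features if f.gene_name == name)
    if lay is not None:
        jlb, ir_len, jsa = lay.jlb, lay.ir_len, lay.jsa
    exons = []
    for s, e in src.exons:
        # IRb offset i maps to IRa offset ir_len - (i - jlb)
        ms = jsa + ir_len - (e - jlb)
        me = jsa + ir_len - (s - jlb)
        exons.append((ms, me))
    exons.sort()
    return replace(
        src,
        strand="-" if src.strand == "+" else "+",
        exons=exons,
        copy_index=1,
    )


def _spliced_genome_coords(feat: GeneFeature) -> list[int]:
    """Genome coordinates of each spliced CDS base in translation order."""
    coords: list[int] = []
    for s, e in feat.exons:
        coords.extend(range(s, e))
    if feat.strand == "-":
        coords.reverse()
    return coords


def _plant_snp(
    core: list[str],
    core_b: list[str],
    feat: GeneFeature,
    spec: SnpSpec,
    rng: np.random.Generator,
    used_sites: set[tuple[str, int]],
    lay: _Layout,
    n_a: int,
) -> list[TruthSnp]:
    coords = _spliced_genome_coords(feat)
    cds = "".join(
        core[c] if feat.strand == "+" else COMPLEMENT[core[c]] for c in coords
    )
    n_codons = len(cds) // 3
    order = list(rng.permutation(np.arange(1, n_codons - 1)))
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for codon_idx in order:
        pos0 = codon_idx * 3 + (spec.codon_position - 1)
        if (feat.gene_name, pos0) in used_sites:
            continue
        # keep junction-spanning genes editable only in their single-copy part
        coord = coords[pos0]
        if feat.gene_name in ("jsbGene",) and coord < lay.jsb:
            continue
        ref_codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        ref = ref_codon[spec.codon_position - 1]
        if spec.substitution_class == "transition":
            alts = [transitions[ref]]
        else:
            alts = [b for b in "ACGT" if b != ref and b != transitions[ref]]
        if spec.ts_subtype == "A<->G":
            if ref not in "AG":
                continue
        elif spec.ts_subtype == "C<->T":
            if ref not in "CT":
                continue
        rng.shuffle(alts)
        for alt in alts:
            alt_codon = (
                ref_codon[: spec.codon_position - 1]
                + alt
                + ref_codon[spec.codon_position :]
            )
            if _translate(alt_codon) == "*":
                continue
            effect = (
                "synonymous"
                if _translate(ref_codon) == _translate(alt_codon)
                else "nonsynonymous"
            )
            if effect != spec.coding_effect:
                continue
            # plant
            written = alt if feat.strand == "+" else COMPLEMENT[alt]
            core_b[coord] = written
            used_sites.add((feat.gene_name, pos0))
            sub_class = spec.substitution_class
            subtype = (
                ("A<->G" if {ref, alt} == {"A", "G"} else "C<->T")
                if sub_class == "transition"
                else "none"
            )
            return [
                TruthSnp(
                    gene=feat.gene_name,
                    copy_index=feat.copy_index,
                    gene_position=pos0 + 1,
                    ref_base=ref,
                    alt_base=alt,
                    ref_codon=ref_codon,
                    alt_codon=alt_codon,
                    substitution_class=sub_class,
                    ts_subtype=subtype,
                    coding_effect=spec.coding_effect,
                    genome_a_position=coord,
                )
            ]
    raise SpecError(f"infeasible SNP spec: {spec}")


def _expand_ir_snps(
    snps: list[TruthSnp], ir_feat: GeneFeature | None, lay: _Layout, n_a: int
) -> list[TruthSnp]:
    if ir_feat is None:
        return snps
    out = list(snps)
    for rec in snps:
        if rec.gene != ir_feat.gene_name:
            continue
        # the IRa copy carries the identical spliced sequence and change
        pos = rec.genome_a_position
        mirror = lay.jsa + lay.ir_len - 1 - (pos - lay.jlb)
        out.append(
            replace(rec, copy_index=1, genome_a_position=mirror)
        )
    return out


def _indel_sites(
    config: SyntheticConfig,
    lay: _Layout,
    features: list[GeneFeature],
    planted_ssrs: list[dict],
) -> list[int]:
    """Deterministic intergenic positions for the requested indels."""
    spans = [f.span(lay.core_len) for f in features]
    spans += [(p["start"] - 2, p["end"] + 2) for p in planted_ssrs]

    def free(pos: int, margin: int = 30) -> bool:
        return all(e <= pos - margin or pos + margin <= s for s, e in spans)

    sites: list[int] = []
    for spec in config.indel_spec:
        if spec.region == "LSC":
            lo, hi = 30, lay.jlb - 30
        elif spec.region == "SSC":
            lo, hi = lay.jsb + 30, lay.jsa - 30
        else:
            raise SpecError(f"indels only supported in LSC/SSC, not {spec.region}")
        pos = next(
            (
                p
                for p in range(hi - 1, lo, -7)
                if free(p) and all(abs(p - q) > 60 for q in sites)
            ),
            None,
        )
        if pos is None:
            raise SpecError(f"no intergenic site for indel {spec}")
        sites.append(pos)
    return sites


def write_pair(
    outdir: str | Path, config: SyntheticConfig | None = None
) -> TruthTable:
    """Generate a pair and write FASTA + GFF3 + truth TSVs to ``outdir``."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_a, genome_b, annot_a, annot_b, truth = generate_pair(config)
    write_fasta([genome_a], outdir / "genomeA.fasta")
    write_fasta([genome_b], outdir / "genomeB.fasta")
    write_annotations(annot_a, outdir / "genomeA.gff3")
    write_annotations(annot_b, outdir / "genomeB.gff3")
    pd.DataFrame([vars(s) for s in truth.snps]).to_csv(
        outdir / "truth_snps.tsv", sep="\t", index=False
    )
    pd.DataFrame([vars(s) for s in truth.ssrs]).to_csv(
        outdir / "truth_ssrs.tsv", sep="\t", index=False
    )
    pd.DataFrame([vars(s) for s in truth.indels]).to_csv(
        outdir / "truth_indels.tsv", sep="\t", index=False
    )
    return truth
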