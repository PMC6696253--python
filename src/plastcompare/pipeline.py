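"""Orchestration of the full two-genome comparison.

``run_compare`` sequences the stages — structure detection, whole-genome
alignment, sliding-window Pi + hotspots, per-gene K2P/Ka/Ks, SNP calling,
codon usage/RSCU, junction offsets and SSR scanning — and writes a
deterministic TSV report bundle plus a JSON manifest of all parameters.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment import anchor_align
from .codon_usage import aa_frequencies, count_codons, round_half_up, rscu
from .divergence import detect_hotspots, gene_divergence, sliding_pi
from .errors import PlastcompareError
from .genome_io import (
    AnnotationSet,
    GenomeRecord,
    extract_cds,
    read_annotations,
    read_fasta,
)
from .ir_structure import find_inverted_repeats, junction_offsets
from .snp import call_snps, summarize_snps
from .ssr import PRESETS, classify_motifs, compound_spans, find_ssrs, join_compounds

_HEADER = "# plastcompare report; coordinates 1-based inclusive unless noted\n"


@dataclass
class RunConfig:
    genome_a: str
    genome_b: str
    annotations_a: str
    annotations_b: str
    outdir: str
    window: int = 600
    step: int = 200
    hotspot_threshold: float = 0.006
    ssr_preset: str = "strict"
    flank: int = 1000
    ir_min_len: int = 1000
    skip_trans_spliced: bool = True

    def validate(self) -> None:
        for path in (self.genome_a, self.genome_b,
                     self.annotations_a, self.annotations_b):
            if not Path(path).exists():
                raise FileNotFoundError(path)
        if min(self.window, self.step, self.flank, self.ir_min_len) < 1:
            raise ValueError("numeric parameters must be positive")
        if self.step > self.window:
            raise ValueError("step must not exceed window")


@dataclass
class StructureComparison:
    deltas: dict[str, int]  # region -> length(A) - length(B)
    total_delta: int


def validate_structure(partition_a, partition_b) -> StructureComparison:
    """Signed per-region length differences (A minus B); the IR delta is
    counted twice in the total, once per copy."""
    deltas = {
        "LSC": partition_a.lsc.length - partition_b.lsc.length,
        "IR": partition_a.irb.length - partition_b.irb.length,
        "SSC": partition_a.ssc.length - partition_b.ssc.length,
    }
    total = deltas["LSC"] + 2 * deltas["IR"] + deltas["SSC"]
    return StructureComparison(deltas=deltas, total_delta=total)


def _shared_cds_pairs(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    annot_a: AnnotationSet,
    annot_b: AnnotationSet,
    skip_trans_spliced: bool = True,
) -> list[tuple[str, int, str, str]]:
    cds_a = {
        (g, c): s for g, c, s in extract_cds(genome_a, annot_a, skip_trans_spliced)
    }
    cds_b = {
        (g, c): s for g, c, s in extract_cds(genome_b, annot_b, skip_trans_spliced)
    }
    return [
        (g, c, cds_a[(g, c)], cds_b[(g, c)])
        for (g, c) in sorted(set(cds_a) & set(cds_b))
    ]


def run_compare(config: RunConfig) -> dict:
    """Run the full comparison; returns the in-memory results and writes
    the TSV/JSON bundle to ``config.outdir``.

    Any stage failure removes partial outputs and re-raises with the
    stage name attached.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        genome_a = read_fasta(config.genome_a)[0]
        genome_b = read_fasta(config.genome_b)[0]
        annot_a = read_annotations(config.annotations_a)
        annot_b = read_annotations(config.annotations_b)

        stage = "structure"
        part_a = find_inverted_repeats(genome_a, min_len=config.ir_min_len)
        part_b = find_inverted_repeats(genome_b, min_len=config.ir_min_len)
        structure = validate_structure(part_a, part_b)
        struct_df = pd.DataFrame(
            {
                "region": ["LSC", "IRb", "SSC", "IRa", "total"],
                f"{genome_a.id}_bp": [
                    part_a.lsc.length, part_a.irb.length, part_a.ssc.length,
                    part_a.ira.length, genome_a.length,
                ],
                f"{genome_b.id}_bp": [
                    part_b.lsc.length, part_b.irb.length, part_b.ssc.length,
                    part_b.ira.length, genome_b.length,
                ],
            }
        )
        struct_df["delta_bp"] = (
            struct_df.iloc[:, 1] - struct_df.iloc[:, 2]
        )
        written.append(_write(outdir / "structure.tsv", struct_df))

        stage = "alignment"
        amap = anchor_align(genome_a.sequence, genome_b.sequence)

        stage = "nucleotide_diversity"
        track = sliding_pi(amap.columns, window=config.window, step=config.step)
        pi_df = pd.DataFrame(
            {
                "start": [w.window_start + 1 for w in track],
                "end": [w.window_end for w in track],
                "valid_sites": [w.valid_sites for w in track],
                "differences": [w.differences for w in track],
                "pi": [w.pi if w.pi is not None else float("nan") for w in track],
                "partial": [w.partial for w in track],
            }
        )
        written.append(_write(outdir / "pi_track.tsv", pi_df))
        hotspots = detect_hotspots(track, threshold=config.hotspot_threshold)
        hs_df = pd.DataFrame(
            {
                "start": [h.start + 1 for h in hotspots],
                "end": [h.end for h in hotspots],
                "n_windows": [h.n_windows for h in hotspots],
                "max_pi": [h.max_pi for h in hotspots],
            }
        )
        written.append(_write(outdir / "hotspots.tsv", hs_df))

        stage = "gene_divergence"
        pairs = _shared_cds_pairs(
            genome_a, genome_b, annot_a, annot_b, config.skip_trans_spliced
        )
        from .alignment import align_gene_pair

        divs = [
            gene_divergence(g, c, align_gene_pair(a, b)) for g, c, a, b in pairs
        ]
        div_df = pd.DataFrame([asdict(d) for d in divs])
        written.append(_write(outdir / "gene_divergence.tsv", div_df))

        stage = "snps"
        snps = call_snps(pairs)
        snp_df = pd.DataFrame([asdict(s) for s in snps])
        written.append(_write(outdir / "snps.tsv", snp_df))
        summary = summarize_snps(snps)

        stage = "codon_usage"
        usage = {}
        for genome, annot in ((genome_a, annot_a), (genome_b, annot_b)):
            table = count_codons(
                extract_cds(genome, annot, config.skip_trans_spliced)
            )
            rt = rscu(table)
            freqs = aa_frequencies(table)
            usage[genome.id] = {
                "total_codons": table.total_codons,
                "table": rt,
                "aa_percent": freqs,
            }
            codon_df = pd.DataFrame(
                [
                    {
                        "amino_acid": e.amino_acid,
                        "aa_name": e.aa_name,
                        "codon": e.codon,
                        "count": e.count,
                        "rscu": (
                            round_half_up(e.rscu, 3) if e.rscu is not None
                            else float("nan")
                        ),
                    }
                    for e in rt.entries
                ]
            )
            written.append(_write(outdir / f"codon_usage_{genome.id}.tsv", codon_df))

        stage = "junctions"
        junction_rows = []
        for part, annot, gid in (
            (part_a, annot_a, genome_a.id),
            (part_b, annot_b, genome_b.id),
        ):
            for j in junction_offsets(part, annot, flank=config.flank):
                junction_rows.append({"genome": gid, **asdict(j)})
        written.append(_write(outdir / "junctions.tsv", pd.DataFrame(junction_rows)))

        stage = "ssr"
        ssr_results = {}
        for genome in (genome_a, genome_b):
            records = join_compounds(
                find_ssrs(genome.sequence, PRESETS[config.ssr_preset])
            )
            by_class, by_unit = classify_motifs(records)
            ssr_results[genome.id] = records
            ssr_df = pd.DataFrame(
                [
                    {
                        "ssr": r.label,
                        "motif_class": r.normalized_class,
                        "size_bp": r.size,
                        "start": r.start,
                        "end": r.end,
                        "compound": r.compound_id or "",
                    }
                    for r in records
                ]
            )
            written.append(_write(outdir / f"ssr_{genome.id}.tsv", ssr_df))

        stage = "manifest"
        manifest = {
            "plastcompare_version": __version__,
            "parameters": asdict(config),
            "snp_summary": asdict(summary),
            "n_shared_cds": len(pairs),
            "n_hotspots": len(hotspots),
            "structure_deltas": structure.deltas,
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(manifest_path)
    except PlastcompareError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    return {
        "structure": structure,
        "partitions": (part_a, part_b),
        "alignment": amap,
        "pi_track": track,
        "hotspots": hotspots,
        "gene_divergence": divs,
        "snps": snps,
        "snp_summary": summary,
        "codon_usage": usage,
        "ssrs": ssr_results,
    }


def _write(path: Path, df: pd.DataFrame) -> Path:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, sep="\t", index=False)
    return path
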