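"""SNP calling and classification within aligned coding sequences.

Positions are 1-based on the spliced, strand-corrected coding sequence of
the reference genome (genome A), the coordinate style used in published
plastome SNP tables.  Each changed base yields one record; the bases of a
multi-hit codon share the codon-level amino-acid comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import gcd
from typing import Iterable, Sequence

from .alignment import align_gene_pair
from .divergence import VALID_BASES, is_transition, translate_codon
from .errors import FormatError

logger = logging.getLogger(__name__)


@dataclass
class SnpRecord:
    gene_name: str
    copy_index: int
    gene_position: int  # 1-based on the spliced coding sequence
    codon_index: int  # 1-based codon number
    codon_position: int  # 1, 2 or 3
    ref_base: str
    alt_base: str
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    substitution_class: str  # transition | transversion
    ts_subtype: str  # "A<->G" | "C<->T" | "none"
    coding_effect: str  # synonymous | nonsynonymous
    multi_hit: bool = False  # codon changed at more than one position


def classify_substitution(ref_base: str, alt_base: str) -> tuple[str, str]:
    """(transition|transversion, subtype): A<->G and C<->T are transitions."""
    for b in (ref_base, alt_base):
        if b not in VALID_BASES:
            raise FormatError(f"invalid base {b!r}")
    if ref_base == alt_base:
        raise ValueError("bases are identical; not a substitution")
    if is_transition(ref_base, alt_base):
        subtype = "A<->G" if {ref_base, alt_base} == {"A", "G"} else "C<->T"
        return "transition", subtype
    return "transversion", "none"


def coding_effect(ref_codon: str, alt_codon: str) -> str:
    """synonymous iff both codons translate identically (plastid code)."""
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or set(codon) - VALID_BASES:
            raise FormatError(f"invalid codon {codon!r}")
    return (
        "synonymous"
        if translate_codon(ref_codon) == translate_codon(alt_codon)
        else "nonsynonymous"
    )


def call_snps(
    cds_pairs: Iterable[tuple[str, int, str, str]]
) -> list[SnpRecord]:
    """Call substitutions in aligned CDS pairs.

    ``cds_pairs`` holds ``(gene_name, copy_index, cdsA, cdsB)``; each pair
    is globally aligned and every mismatching gap-free column becomes one
    record.  Mismatches adjacent to a gap column are skipped with a
    warning (indel shadows, not point substitutions).
    """
    records: list[SnpRecord] = []
    for gene_name, copy_index, cds_a, cds_b in cds_pairs:
        columns = align_gene_pair(cds_a, cds_b)
        gapped = [("-" in col) for col in columns]
        pos_a = 0
        mismatch_cols: list[tuple[int, int, str, str]] = []  # (col, posA, a, b)
        for i, (a, b) in enumerate(columns):
            if a != "-":
                pos_a += 1
            if "-" in (a, b):
                continue
            if a == b or a not in VALID_BASES or b not in VALID_BASES:
                continue
            near_gap = (i > 0 and gapped[i - 1]) or (
                i < len(columns) - 1 and gapped[i + 1]
            )
            if near_gap:
                logger.warning(
                    "%s: mismatch at coding position %d adjoins an indel; "
                    "skipped",
                    gene_name,
                    pos_a,
                )
                continue
            mismatch_cols.append((i, pos_a, a, b))
        # group by codon to attach codon context and the shared aa change
        hits_per_codon: dict[int, int] = {}
        for _, pos, _, _ in mismatch_cols:
            ci = (pos - 1) // 3 + 1
            hits_per_codon[ci] = hits_per_codon.get(ci, 0) + 1
        for _, pos, a, b in mismatch_cols:
            codon_index = (pos - 1) // 3 + 1
            codon_pos = (pos - 1) % 3 + 1
            ref_codon = cds_a[(codon_index - 1) * 3 : codon_index * 3]
            alt_codon = _alt_codon(ref_codon, mismatch_cols, codon_index)
            sub_class, subtype = classify_substitution(a, b)
            records.append(
                SnpRecord(
                    gene_name=gene_name,
                    copy_index=copy_index,
                    gene_position=pos,
                    codon_index=codon_index,
                    codon_position=codon_pos,
                    ref_base=a,
                    alt_base=b,
                    ref_codon=ref_codon,
                    alt_codon=alt_codon,
                    ref_aa=translate_codon(ref_codon),
                    alt_aa=translate_codon(alt_codon),
                    substitution_class=sub_class,
                    ts_subtype=subtype,
                    coding_effect=coding_effect(ref_codon, alt_codon),
                    multi_hit=hits_per_codon[codon_index] > 1,
                )
            )
    return records


def _alt_codon(
    ref_codon: str,
    mismatches: Sequence[tuple[int, int, str, str]],
    codon_index: int,
) -> str:
    alt = list(ref_codon)
    for _, pos, _, b in mismatches:
        if (pos - 1) // 3 + 1 == codon_index:
            alt[(pos - 1) % 3] = b
    return "".join(alt)


@dataclass
class SnpSummary:
    total: int
    transitions: int
    transversions: int
    ts_ag: int
    ts_ct: int
    synonymous: int
    nonsynonymous: int
    both_substitution_codons: int
    ts_tv_ratio: str  # reduced, e.g. "1:1"


def summarize_snps(records: Sequence[SnpRecord]) -> SnpSummary:
    ts = sum(r.substitution_class == "transition" for r in records)
    tv = sum(r.substitution_class == "transversion" for r in records)
    by_codon: dict[tuple[str, int, int], set[str]] = {}
    for r in records:
        by_codon.setdefault(
            (r.gene_name, r.copy_index, r.codon_index), set()
        ).add(r.substitution_class)
    both = sum(
        1 for classes in by_codon.values()
        if {"transition", "transversion"} <= classes
    )
    if ts and tv:
        g = gcd(ts, tv)
        ratio = f"{ts // g}:{tv // g}"
    else:
        ratio = f"{ts}:{tv}"
    return SnpSummary(
        total=len(records),
        transitions=ts,
        transversions=tv,
        ts_ag=sum(r.ts_subtype == "A<->G" for r in records),
        ts_ct=sum(r.ts_subtype == "C<->T" for r in records),
        synonymous=sum(r.coding_effect == "synonymous" for r in records),
        nonsynonymous=sum(r.coding_effect == "nonsynonymous" for r in records),
        both_substitution_codons=both,
        ts_tv_ratio=ratio,
    )
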