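"""Codon counting, relative synonymous codon usage and amino-acid frequencies.

Conventions follow plastome usage tables: codons are displayed in the RNA
alphabet (AUGC); the first codon of every CDS is assigned to the
methionine family regardless of identity (plastid alternative starts AUA
and GUG initiate with fMet), giving a three-codon Met family; the three
stop codons form their own family and are included in the codon total.
RSCU of a codon is its count divided by the mean count of its family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .divergence import translate_codon
from .errors import IntegrityError

RNA_CODONS = [
    a + b + c for a in "UCAG" for b in "UCAG" for c in "UCAG"
]

AA_NAMES = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr", "*": "Ter",
}

START_RECODED = {"AUA", "GUG"}  # alternative plastid starts, counted as Met


def to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal half-up rounding (the convention of printed usage tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CodonCountTable:
    """Codon occurrence counts; ``start_counts`` tracks first-codon
    occurrences so alternative starts can be re-assigned to Met."""

    counts: dict[str, int] = field(default_factory=dict)  # RNA codon -> n
    start_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def recoded_starts(self) -> int:
        return sum(
            n for codon, n in self.start_counts.items()
            if codon in START_RECODED
        )


def count_codons(
    cds_list: Iterable[tuple[str, int, str] | str]
) -> CodonCountTable:
    """Count in-frame codons over a CDS collection.

    Accepts plain coding strings or ``(gene, copy_index, cds)`` triples as
    produced by :func:`plastcompare.genome_io.extract_cds`.
    """
    table = CodonCountTable()
    for item in cds_list:
        gene, cds = ("?", item) if isinstance(item, str) else (item[0], item[2])
        if len(cds) % 3:
            raise IntegrityError(
                f"{gene}: CDS length {len(cds)} not a multiple of 3"
            )
        for i in range(0, len(cds), 3):
            codon = to_rna(cds[i : i + 3])
            if "N" in codon:
                continue
            table.counts[codon] = table.counts.get(codon, 0) + 1
            if i == 0:
                table.start_counts[codon] = table.start_counts.get(codon, 0) + 1
    return table


def _families(table: CodonCountTable) -> dict[str, dict[str, int]]:
    """Partition counts into RSCU families.

    Met = {AUG, AUA*, GUG*} (* = start occurrences only); the AUA and GUG
    occurrences outside start position stay with Ile and Val; stops form
    the Ter family; remaining codons group by encoded amino acid.
    """
    families: dict[str, dict[str, int]] = {}
    for codon in RNA_CODONS:
        n = table.counts.get(codon, 0)
        if codon in START_RECODED:
            n_start = table.start_counts.get(codon, 0)
            families.setdefault("M", {})[codon] = n_start
            n -= n_start
        aa = translate_codon(to_dna(codon))
        families.setdefault(aa, {})[codon] = n
    return families


@dataclass
class RscuEntry:
    amino_acid: str  # one-letter symbol, '*' for terminator
    aa_name: str
    codon: str
    count: int
    rscu: float | None  # None when the whole family is unobserved


@dataclass
class RscuTable:
    entries: list[RscuEntry]
    total_codons: int

    def get(self, codon: str, amino_acid: str | None = None) -> RscuEntry:
        for e in self.entries:
            if e.codon == codon and (amino_acid is None or e.amino_acid == amino_acid):
                return e
        raise KeyError(codon)


def rscu(table: CodonCountTable) -> RscuTable:
    """RSCU per codon: count / (family total / family size)."""
    entries: list[RscuEntry] = []
    for aa, members in sorted(_families(table).items()):
        family_total = sum(members.values())
        size = len(members)
        for codon in sorted(members):
            n = members[codon]
            value = None if family_total == 0 else n / (family_total / size)
            entries.append(
                RscuEntry(
                    amino_acid=aa,
                    aa_name=AA_NAMES[aa],
                    codon=codon,
                    count=n,
                    rscu=value,
                )
            )
    return RscuTable(entries=entries, total_codons=table.total_codons)


def family_counts(table: CodonCountTable) -> dict[str, int]:
    return {
        aa: sum(members.values()) for aa, members in _families(table).items()
    }


def aa_frequencies(table: CodonCountTable) -> dict[str, float]:
    """Percent of total codons per amino-acid family (stops included in
    both a Ter entry and the denominator)."""
    total = table.total_codons
    if total == 0:
        raise IntegrityError("empty codon table")
    return {
        aa: 100.0 * n / total for aa, n in sorted(family_counts(table).items())
    }


def table_from_counts(
    counts: Mapping[str, int], start_counts: Mapping[str, int] | None = None
) -> CodonCountTable:
    """Build a table from externally tabulated per-codon counts (e.g. a
    published usage table); keys may be RNA or DNA codons."""
    return CodonCountTable(
        counts={to_rna(c): int(n) for c, n in counts.items()},
        start_counts={to_rna(c): int(n) for c, n in (start_counts or {}).items()},
    )
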