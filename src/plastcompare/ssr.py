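"""MISA-style perfect microsatellite (SSR) scanning.

Detects maximal perfect tandem runs of 1-6 bp units under a per-unit-size
minimum-repeat threshold, attributes each run to its smallest repeating
unit, joins nearby SSRs into compound formations, and normalizes motifs
into strand/rotation classes (A/T, C/G, ...).

Three presets mirror common plastome survey parameterizations:

========  ==================================================
name      unit_size -> min repeats
========  ==================================================
strict            1/10 2/6 3/5 4/5 5/5 6/5
melotto_modified  1/8  2/5 3/3 4/3 5/3 6/3
relaxed           1/10 2/5 3/4 4/3 5/2 6/2
========  ==================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genome_io import reverse_complement


@dataclass(frozen=True)
class SsrPreset:
    name: str
    thresholds: Mapping[int, int]  # unit size (1..6) -> min repeat count

    def __post_init__(self) -> None:
        if set(self.thresholds) != set(range(1, 7)):
            raise ValueError("thresholds must cover unit sizes 1..6")
        if any(v < 1 for v in self.thresholds.values()):
            raise ValueError("min_repeats must be >= 1")


PRESETS = {
    "strict": SsrPreset("strict", {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}),
    "melotto_modified": SsrPreset(
        "melotto_modified", {1: 8, 2: 5, 3: 3, 4: 3, 5: 3, 6: 3}
    ),
    "relaxed": SsrPreset("relaxed", {1: 10, 2: 5, 3: 4, 4: 3, 5: 2, 6: 2}),
}


def normalize_motif_class(motif: str) -> str:
    """Canonical class label merging rotations and reverse complements,
    e.g. A and T -> "A/T", G and C -> "C/G", AT and TA -> "AT/AT"."""
    fwd = min(motif[i:] + motif[:i] for i in range(len(motif)))
    rc = reverse_complement(motif)
    rev = min(rc[i:] + rc[:i] for i in range(len(rc)))
    return "/".join(sorted([fwd, rev]))


@dataclass
class SsrRecord:
    motif: str
    repeats: int
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    compound_id: str | None = None

    @property
    def unit_size(self) -> int:
        return len(self.motif)

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def normalized_class(self) -> str:
        return normalize_motif_class(self.motif)

    @property
    def label(self) -> str:
        return f"({self.motif}){self.repeats}"


def _minimal_period(unit: str) -> int:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return p
    return len(unit)


def find_ssrs(sequence: str, preset: SsrPreset | str = "strict") -> list[SsrRecord]:
    """Maximal perfect tandem runs meeting the preset thresholds.

    Runs are attributed to their smallest repeating unit ("ATATAT" is one
    dinucleotide SSR, not three mononucleotide pairs); when runs of
    different unit sizes overlap, the smaller unit wins.  Only full repeat
    units count (a trailing partial unit is not part of the SSR).
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    seq = sequence.upper()
    n = len(seq)
    candidates: list[SsrRecord] = []
    for u in range(1, 7):
        min_rep = preset.thresholds[u]
        i = 0
        while i + u <= n:
            unit = seq[i : i + u]
            if "N" in unit or _minimal_period(unit) != u:
                i += 1
                continue
            # extend full-unit repeats
            j = i + u
            while j + u <= n and seq[j : j + u] == unit:
                j += u
            repeats = (j - i) // u
            if repeats >= min_rep:
                # base-level left maximality: one tandem locus is reported
                # once, from its leftmost phase, not per unit rotation
                if i == 0 or seq[i - 1] != seq[i + u - 1]:
                    candidates.append(
                        SsrRecord(motif=unit, repeats=repeats, start=i + 1, end=j)
                    )
                    i = j
                else:
                    i += 1
            else:
                i += 1
    # smaller unit size wins on overlap
    candidates.sort(key=lambda r: (r.unit_size, r.start))
    kept: list[SsrRecord] = []
    for rec in candidates:
        if any(
            rec.start <= other.end and other.start <= rec.end
            for other in kept
            if other.unit_size < rec.unit_size
        ):
            continue
        kept.append(rec)
    kept.sort(key=lambda r: r.start)
    return kept


def join_compounds(
    records: Sequence[SsrRecord], max_gap: int = 100
) -> list[SsrRecord]:
    """Assign a shared ``compound_id`` to consecutive SSRs separated by at
    most ``max_gap`` unrepeated bases.

    Constituents retain their individual identity (and are counted
    individually in SSR totals); the compound span runs from the first
    constituent's start to the last one's end.
    """
    records = sorted(records, key=lambda r: r.start)
    groups: list[list[SsrRecord]] = []
    for rec in records:
        if groups and rec.start - groups[-1][-1].end - 1 <= max_gap:
            groups[-1].append(rec)
        else:
            groups.append([rec])
    out: list[SsrRecord] = []
    c = 0
    for group in groups:
        cid = None
        if len(group) > 1:
            c += 1
            cid = f"C{c}"
        for rec in group:
            out.append(
                SsrRecord(
                    motif=rec.motif,
                    repeats=rec.repeats,
                    start=rec.start,
                    end=rec.end,
                    compound_id=cid,
                )
            )
    return out


def compound_spans(records: Sequence[SsrRecord]) -> dict[str, tuple[int, int, int]]:
    """Per compound: (start, end, span size in bp)."""
    spans: dict[str, tuple[int, int, int]] = {}
    for rec in records:
        if rec.compound_id is None:
            continue
        if rec.compound_id in spans:
            s, e, _ = spans[rec.compound_id]
            s, e = min(s, rec.start), max(e, rec.end)
        else:
            s, e = rec.start, rec.end
        spans[rec.compound_id] = (s, e, e - s + 1)
    return spans


def classify_motifs(
    records: Iterable[SsrRecord],
) -> tuple[dict[str, int], dict[int, int]]:
    """Counts by normalized motif class and by unit size."""
    by_class: dict[str, int] = {}
    by_unit: dict[int, int] = {}
    for rec in records:
        by_class[rec.normalized_class] = by_class.get(rec.normalized_class, 0) + 1
        by_unit[rec.unit_size] = by_unit.get(rec.unit_size, 0) + 1
    return by_class, by_unit
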