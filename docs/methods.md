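# Methods

This note records the models and conventions behind each stage, the
defaults and why they were chosen, and what the synthetic data generator
does and does not emulate.

## Coordinates and alphabets

File boundaries follow the formats: FASTA, and GFF3 with 1-based
inclusive coordinates. Internally every coordinate is 0-based half-open;
report tables state their convention in a header comment. Sequences are
normalized to uppercase over {A, C, G, T, N}: U maps to T, IUPAC
ambiguity codes collapse to N, anything else is a format error. N bases
are excluded from every downstream site count. Circular genomes are
linearized at the conventional LSC start; features may wrap the origin
(an exon with end ≤ start on a circular record) and are resolved by
modular index arithmetic.

## Whole-genome alignment

Two conspecific plastomes differ by point substitutions and a handful of
short indels, so a full dynamic-programming alignment is unnecessary.
`anchor_align` indexes k-mers that are unique in each genome (k = 21;
21-mers are effectively unique at the 140 kb scale), keeps the longest
strictly-increasing chain of shared anchors, collapses same-diagonal
anchors into exact blocks, and closes the short inter-block segments with
a global alignment (match +1, mismatch −1, gap −2, N mismatch-neutral at
0). Gap costs are linear: at the divergence levels involved (< 0.1%)
affine gaps change nothing, and the scores are configurable. A chain
covering less than half of either genome aborts with a co-linearity
error — this is the signature of an inversion or rearrangement, which
the method deliberately does not model. On sequences with only point
edits the result provably scores the same as the unrestricted global
alignment; the test suite checks this against the full-DP oracle.

## Nucleotide diversity and hotspots

For two aligned sequences, nucleotide diversity per window reduces to
the p-distance over valid columns. Windows tile genome-A coordinates at
every step offset (600 bp window, 200 bp step by default); trailing
windows truncated by the sequence end are kept and flagged partial.
Columns with a gap or N in either sequence are excluded from numerator
and denominator alike (pairwise complete deletion), so 0 ≤ Pi ≤ 1 always
holds and a window with no valid column reports Pi as undefined rather
than 0. Hotspot calling flags windows with Pi **strictly** greater than
the threshold (default 0.006) and merges adjacent flagged windows,
reporting each region's maximum.

## K2P distance

With P and Q the transition (A↔G, C↔T) and transversion proportions over
valid columns, `d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)`. The correction
never shrinks the p-distance (d ≥ P + Q). When an argument of a
logarithm is non-positive the distance is saturated and a saturation
error is raised rather than a number returned.

## Ka/Ks (NG86)

The Nei–Gojobori (1986) counting method: synonymous site counts are
fractional per codon position (changes to stop codons count as
nonsynonymous), averaged over the two sequences; codons differing at
more than one position average their synonymous/nonsynonymous difference
counts over all minimal substitution pathways, discarding pathways that
pass through a stop codon unless all do; pN and pS receive the
Jukes–Cantor correction d = −¾·ln(1 − 4p/3). Translation uses the
bacterial/plastid code (table 11), whose codon assignments equal the
standard code. Ka/Ks is undefined when Ks = 0 (reported as such, never
as infinity); a gene with Ka = 0 and Ks > 0 is classed as very strong
purifying selection. NG86 was chosen as a transparent, exactly testable
counting method — an exhaustive pathway-enumeration oracle verifies all
3,721 sense-codon pairs in the suite — and results can differ from
likelihood or approximate methods (γ-MYN and others) implemented in
dedicated calculators. By default a saturated correction raises a
saturation error; `on_saturation="inf"` returns +inf instead, which is
the convention needed to express single-codon worked examples where pS
reaches 1.

## SNP records

SNPs are called per homologous CDS pair after global alignment.
Positions are 1-based on the spliced, strand-corrected coding sequence —
the coordinate style of published plastome SNP tables — so codon index
and codon position follow arithmetically. Mismatches in a column
adjacent to an indel are skipped with a warning (indel shadows, not
substitutions). A codon hit at several positions yields one record per
changed base; all records of that codon share the whole-codon amino-acid
comparison and are flagged multi-hit so other conventions can be applied
downstream. IR-duplicated genes yield records per copy.

## Codon usage and RSCU

Codons are counted in frame over every CDS (trans-spliced genes excluded
by default, toggleable). The first codon of each CDS belongs to the
methionine family regardless of identity: plastid genes initiate with
fMet from the alternative starts AUA and GUG as well as AUG, which is
why usage tables list AUA both under isoleucine (internal occurrences)
and methionine (start occurrences). The three stop codons form their own
family and are included in the codon total — amino-acid percentages are
family counts over that total. RSCU of a codon is its count divided by
its family's mean count; a family with no observations reports RSCU as
undefined. Displayed values round half-up to 3 decimals (RSCU) or 2–3
decimals (percentages), matching the convention of published tables.

## Quadripartite structure and junctions

The IR pair is found by seed-and-extend against the genome's reverse
complement: every exact seed match is extended maximally (with circular
wrap-around) and the longest disjoint pair of segments, one the exact
reverse complement of the other, defines IRb (the copy following the
LSC) and IRa. Exact matching is the default because the two IR copies of
these genomes are identical; detection is invariant to rotation of the
circular sequence up to a coordinate shift. The LSC is the longer
inter-IR arc, the SSC the shorter. Junctions are named JLB (LSC/IRb),
JSB (IRb/SSC), JSA (SSC/IRa), JLA (IRa/LSC) and sit on the first base of
the downstream region (0-based internally, 1-based in reports).
"Contraction" is the gap in bp between a boundary gene's nearest end and
its junction; "expansion" is a gene overlapping the junction, reported
as bp on each side — the reading consistent with a gene located in the
SSC but extending 29 bp into the IRb.

## SSR scanning

Perfect tandem runs of 1–6 bp units are reported when the number of
complete units meets the per-unit-size threshold of the chosen preset
(`strict` 1/10 2/6 3/5 4/5 5/5 6/5; `melotto_modified` 1/8 2/5 3/3 4/3
5/3 6/3; `relaxed` 1/10 2/5 3/4 4/3 5/2 6/2). One tandem locus is one
SSR: runs are counted from their leftmost phase (base-level left
maximality), the motif must be primitive (its own minimal period), and
when runs of different unit sizes overlap the smaller unit wins. SSRs
separated by at most 100 bp of unrepeated sequence (the MISA
interruption default; observed compound gaps are 8 and 45 bp) share a
compound label; constituents keep their individual identity and are
counted individually in totals. Motif classes merge a motif's rotations
with the rotations of its reverse complement (A/T, C/G, AT/AT, ...).

## Synthetic data generator

`generate_pair` assembles genome A as LSC + IRb + SSC + revcomp(IRb)
over an i.i.d. uniform background, stamps genes into it (single- and
two-exon, both strands, one IR-resident gene annotated in both copies,
and one boundary gene per junction at configurable offsets), plants SSRs
(including two compound formations with 8 bp and 45 bp gaps, spans 28
and 65 bp) and derives genome B by applying the SNP and indel
specifications exactly. Two bases flanking the designed IR boundaries
are pinned so a chance complementary base cannot extend the detected
repeat past the planted junction, and planted SSRs are spaced further
apart than the compound-joining gap. The default configuration is
desk-scale — 14 kb (8400 + 2100 + 1400 + 2100), 12 interior genes, 24
planted SNPs mirroring the published class mix between the two sugarcane
ancestors (12 Ts of which 8 A↔G and 4 C↔T, 12 Tv, 18 nonsynonymous / 6
synonymous, two substitutions duplicated with the IR gene copy), two
short LSC indels (+7/−5 bp) and seven planted SSR runs; a ~140 kb
configuration with the same truth is provided for scale checks. The
same seed reproduces byte-identical output.

What the generator does **not** emulate: GC skew and codon bias (the
background is uniform — Pi, K2P and SSR logic are composition-agnostic,
but composition-sensitive statistics measured on synthetic data would
not transfer to real plastomes), rearrangements/inversions (none exist
between the target genomes), sequencing error, and intergenic
conservation structure. Passing truth-recovery tests therefore
demonstrates correctness of the coordinate arithmetic, classification
and detection logic, not robustness to assembly artifacts.

Some SNP specifications are infeasible by the genetic code — for
example, no synonymous change exists at codon position 2 of any sense
codon — and the generator reports the offending entry rather than
planting something else.

## Numerical and degenerate-input conventions

Undefined quantities are reported as undefined (`None` / flagged), never
as 0: Pi with no valid sites, Ka/Ks with Ks = 0, RSCU of an unobserved
family, K2P past saturation. Display rounding is decimal half-up.
Ties in hotspot merging do not arise (adjacency is positional). The
Ts:Tv ratio is reported reduced by the gcd (e.g. 12:12 → 1:1).

## Problem sizes in the test suite

The suite runs the generator at the 14 kb desk scale (and one ~140 kb
scale check), alignment oracles on 1–2 kb pairs, the NG86 oracle over
all 3,721 sense-codon pairs, and the SSR oracle on random 10–20 kb
sequences — sizes chosen so the whole suite completes in a few seconds
while still exercising every code path at full-genome scale once.
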