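# Methods

## Scope and shape

varprimer is a two-phase tool: (1) design primer/probe sets on a template
extracted from a local reference, (2) interrogate cohort variation at the
designed binding sites and screen genome specificity. The one-shot CLI
(`varprimer design`) is a thin composition of library functions; every
stage (template extraction, candidate enumeration, pairing, coordinate
mapping, frequency annotation, scanning) is independently callable for
step-wise use.

## Coordinates and templates

All genomic coordinates are 1-based inclusive (the GFF3 convention), and
reports print spans as `contig:start-end` with outermost coordinates.
Internally, template positions are 0-based offsets into the template
string.

gDNA/probe templates are the window `position ± flank` around the target,
default flank 500 bp (a choice — large enough to give the 60–120 bp
amplicon search room on either side; CLI-overridable), clipped to the
contig with a warning. cDNA templates are the spliced exon sequence in
transcription order (reverse-complemented for − strand transcripts), with
junction offsets at cumulative exon lengths. Soft-masked (lowercase)
reference sequence is uppercased and treated as normal template, but the
soft-masked fraction of each template is recorded so repeat-heavy designs
are visible; candidates overlapping `N` are discarded (no defined Tm).

## Thermodynamics

Melting temperatures use the unified nearest-neighbor model: Allawi &
SantaLucia (1997) stacking ΔH°/ΔS° with SantaLucia (1998)
initiation and terminal-AT corrections,

    Tm = ΔH° / (ΔS°_salt + R ln(C_T/4)) − 273.15,
    ΔS°_salt = ΔS° + 0.368 (N−1) ln[Na⁺]_eff,
    [Na⁺]_eff (mM) = monovalent + 120 √(max(divalent − dNTP, 0)).

Default reaction conditions are 50 mM monovalent, 1.5 mM Mg²⁺, 0.6 mM
dNTP, 50 nM total oligo (C_T/4 ≈ the excess-primer approximation). These
are the defaults of the de-facto standard design stack, chosen so the
reported Tm of any oligo agrees with what bench users expect from
Primer3-family tools; the test suite pins this agreement against
Biopython's independent implementation of the same model to 1e-6 °C, and
against six published primer Tm values to ±0.3 °C (the slack absorbs the
two-decimal rounding of published tables).

3'-end stability is the ΔG°₃₇ sum of the four NN stacks in the 3'
pentamer, the window where template mismatches are most disruptive to
extension.

### Complementarity screens

Self-dimer, cross-dimer and hairpin screens are ungapped *counting*
screens: the oligo is slid against the reverse of its partner over every
offset and Watson–Crick complementary positions are counted; the
end-anchored variant restricts to alignments covering the oligo's 3'
terminus; the hairpin screen applies the same engine to a sequence against
itself with a minimum loop of 3 nt. This is deliberately not a free-energy
alignment (no DP thermodynamics, no dangling ends): at primer scale the
counting screen is transparent, exactly testable against enumeration, and
adequate to kill the pathological candidates. Because counts run higher
than Primer3's match-minus-mismatch scores, the default caps are set from
the empirical distribution of self-scores of random 45%-GC 20-mers
(90th percentile ≈ 10): `max_any_complementarity = 12`,
`max_end_complementarity = 10`. Oligos above these are unusual, not
typical.

## Candidate enumeration and ranking

Every window of every allowed length (default 18/20/25 min/opt/max) in
both orientations is filtered in a fixed order: non-ACGT, Tm bounds
(57–63 °C), GC bounds (30–70 %), homopolymer run > 4, 3'-terminal
G/C run ≥ 3 (the "GC-clamp cap", on by default to avoid over-sticky 3'
ends; toggleable), self-complementarity caps, hairpin cap. Kill counts per
filter are collected, and a design that returns nothing raises a
structured explain report rather than an empty list — the run statistics
are the troubleshooting surface.

Penalty (lower = better):

    w_tm·|Tm − Tm_opt| + w_len·|len − len_opt| + w_gc·|GC − GC_opt|
    + w_self_any·any + w_self_end·end + w_end_stab·max(0, cap − ΔG_end)

with defaults w_tm = w_len = 1, w_gc = 0.2, w_self_any = 0.1,
w_self_end = 0.2, w_end_stab = 0.1, cap = −9 kcal/mol (ends more stable
than −9 are penalised as mispriming-prone). Pair penalty adds
w_tmdiff·|Tm_f − Tm_r| with w_tmdiff = 1. The weights are engine
conventions, exposed in `DesignParams`; Primer3-style keys
(`PRIMER_MIN_TM`, …) are accepted as config aliases so published parameter
dictionaries port over.

Pairs must satisfy forward-end < reverse-start (no overlap), product size
(reverse 3'-most template base − forward 5' start + 1) inside the amplicon
range (default 60–120 bp), and — for cDNA assays on multi-exon
transcripts — at least one junction-spanning mate. A primer "spans" a
junction when ≥ 4 nt lie on each side (config `junction_anchor`); 4 nt is
the smallest anchor that meaningfully blocks extension on unspliced
template. Single-exon transcripts design normally with an attached
warning. Ranking sorts by (pair_penalty, forward position, product size);
identical coordinate pairs are deduplicated; ties and ordering are fully
deterministic, so reruns are byte-identical.

Internal probes are the best-penalty window strictly between the primers'
3' ends, with their own length/Tm/GC bounds (default 18/24/30 nt,
64/68/72 °C — ~8 °C above primer Tm per hydrolysis-probe practice) and no
5'-terminal G (quenches reporter fluorescence; toggleable). Product sizes
for junction-spanning pairs are cDNA-space (the spliced molecule is the
amplification template).

## Coordinate mapping

A template interval maps to an ordered list of genomic blocks: one block
for contiguous oligos; split at every junction crossed for cDNA oligos.
Blocks are reported on the forward genomic axis with a strand flag, and
the display span uses outermost coordinates — a junction-spanning 20-mer
therefore displays a span longer than 20 bp (it covers the intron). Block
lengths always sum to the oligo length (tested across 100 generator
seeds). The inverse map returns None for intronic/out-of-window positions
and is the exact inverse on exonic bases (round-trip tested). Layout
output draws junction primers "expanded": blocks at the extremities joined
by a dotted line across the intron.

## Cohort variation annotation

The VCF is loaded into an in-memory per-position table (desk-scale files;
no index required for plain-text VCF). For each oligo base, in 5'→3' oligo
order (reverse of genomic order for reverse-reading oligos), the summed
alternate allele frequency is

    Σ_alts  (alt allele count) / (called alleles in cohort)

per site, missing genotypes dropped from the denominator, multiallelic
records summed over alts, capped at 1. Sites absent from the VCF are
invariant (frequency 0). A site where every cohort genotype is missing is
flagged and treated as 0 with a warning. Frequencies are allele-based, not
carrier-based — the natural scale for duplex-destabilisation risk, and the
one on which ref + Σalt = 1 holds exactly.

Cohorts are selected by an AND-combined equality/membership grammar over
metadata columns (`taxon=coluzzii,country=Ghana|Benin`) rather than
arbitrary expression evaluation: restricted, portable, and safely
testable. An empty query selects every sample; an empty *result* is an
error, because a silently empty cohort would make every site look
invariant.

Risk flags: `has_3prime_snp` is a segregating site at frequency ≥
threshold (default 0.05; a 1-in-20 chromosomes chance of a mismatch is
where assays start to notice) within the last five 3' bases. Degenerate
redesigns substitute the IUPAC code covering the oligo base plus all
qualifying alternate alleles (complemented when the oligo reads the
opposite strand from the VCF alleles); degeneracy is the product of
per-base allele counts. Indels are flagged, never degenerated — IUPAC
codes cannot encode length variants.

## Specificity

An 11-mer index of the genome is probed with every seed of the query (both
strands); seeded locations are verified by full-length Hamming distance ≤
max_mismatches (default 2). All overlapping seeds are used, so every exact
occurrence is found for any oligo ≥ 11 nt, and sensitivity is complete up
to ⌊len/11⌋ − 1 mismatches (2 mismatches for ≥ 33 nt; 1 for typical
18–25 nt primers). `naive_scan` provides the exhaustive O(genome×oligo)
audit mode. A pair is non-specific when a forward-oligo hit and a
reverse-oligo hit other than the intended locus sit convergently
(plus-strand hit upstream of minus-strand hit) on one contig within 5 kb
(the spurious-amplicon cap — beyond which short-extension PCR products are
implausible); secondary hits that cannot converge only produce a warning.

## Synthetic fixtures

The generator emits FASTA/GFF3/VCF(4.2)/TSV from a single manifest:
contigs with i.i.d. bases at GC 0.45 (mosquito-like genome-wide GC), genes
of 1–6 exons on both strands, planted SNPs, duplicated segments and
planted oligo copies, and a two-cohort sample table (default 30 + 70
diploids). Genotypes at planted SNPs are *allocated* deterministically —
round(freq × 2n) alternate alleles laid down as homozygotes then at most
one heterozygote, within the target cohort — so recovered frequencies are
exact and tests assert equality, not approximation. Everything is a pure
function of the manifest; same seed ⇒ byte-identical files.

What the fixtures do **not** emulate: real nucleotide composition, linkage
disequilibrium, population structure, Hardy–Weinberg noise, sequencing
missingness patterns, or repeat families. Passing tests therefore
demonstrate algorithmic correctness (coordinate arithmetic, counting,
filtering, scanning) — not that any particular real-genome design is
wet-lab robust.

## Problem sizes and numerical choices

Property sweeps use one-gene fixtures (~0.7–2.5 kb contigs, 20 diploids)
across 50–100 seeds, and a 30 kb three-contig fixture with 100 diploids
for the end-to-end and oracle tests — sizes at which the brute-force
oracles (full window enumeration, per-genotype counting, exhaustive
Hamming scan) are themselves fast enough to run exactly. Tie-breaking is
always lexicographic on documented keys; frequencies are exact rational
arithmetic in floating point (denominators ≤ 200, no accumulated error at
test scale); template-window clipping warns rather than errors; zero
surviving candidates is a structured error, never an empty success.

## Known limitations

- No DP secondary-structure thermodynamics (hairpin/dimer ΔG), no
  dangling-end or coaxial terms; the counting screens are calibrated
  stand-ins.
- No multiplex panel compatibility optimisation — single-locus design
  only.
- Specificity scanning is exhaustive only up to the seed-guarantee bound;
  beyond it (e.g. 2 mismatches on a 20-mer) sensitivity is high but not
  guaranteed — use `naive_scan` to audit.
- The VCF is held in memory; population-scale VCFs should be pre-sliced to
  the design region.
- Frequencies are computed per SNP site; indels and structural variants
  only flag positions.
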