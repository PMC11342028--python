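"""Genome specificity screen for designed oligos.

A seed-and-extend scan: every 11-mer of the query is looked up in a k-mer
index of the reference, and each seeded location is verified by Hamming
distance of the full oligo (both strands scanned).  Overlapping seeds give
full sensitivity whenever the oligo carries at most floor(len/11) - 1
mismatches, so the default cap of 2 mismatches is exhaustive for oligos of
33 nt and longer; typical 18-25 nt primers are exhaustive at <=1 mismatch.
A naive full-genome scan is available for exhaustive audits.

A pair is flagged non-specific when, beyond the intended locus, a hit of
the forward and a hit of the reverse oligo sit on the same contig in
convergent orientation within the spurious-amplicon distance cap — the
configuration from which an unintended PCR product could arise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reference import GenomeRef
from .thermo import reverse_complement

__all__ = [
    "Hit",
    "HitList",
    "GenomeIndex",
    "scan",
    "naive_scan",
    "specificity_report",
]

SEED_SIZE = 11
DEFAULT_MAX_MISMATCHES = 2
DEFAULT_AMPLICON_CAP = 5000


@dataclass(frozen=True)
class Hit:
    contig: str
    start: int      # 1-based position of the oligo's leftmost genomic base
    strand: str     # '+': oligo == genome slice; '-': oligo == revcomp(slice)
    mismatches: int


@dataclass
class HitList:
    oligo: str
    hits: list[Hit]
    max_mismatches: int

    @property
    def unique(self) -> bool:
        return len(self.hits) == 1

    def sorted(self) -> list[Hit]:
        return sorted(self.hits, key=lambda h: (h.contig, h.start, h.strand))


class GenomeIndex:
    """k-mer location index of a reference genome (forward strand only;
    queries are scanned on both strands)."""

    def __init__(self, genome: GenomeRef, k: int = SEED_SIZE):
        self.genome = genome
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in genome.contigs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((contig, i))

    def locations(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _hamming_le(a: str, b: str, cap: int) -> int | None:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return None
    return mm


def scan(
    oligo: str,
    index: GenomeIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> HitList:
    """Seed-and-extend search for all near-exact genomic occurrences of an
    oligo on either strand."""
    L = len(oligo)
    if L < index.k:
        raise ValueError(f"oligo ({L} nt) shorter than seed size {index.k}")
    genome = index.genome
    hits: dict[tuple[str, int, str], int] = {}
    for strand, query in (("+", oligo), ("-", reverse_complement(oligo))):
        candidates: set[tuple[str, int]] = set()
        for off in range(L - index.k + 1):
            for contig, kpos in index.locations(query[off : off + index.k]):
                start0 = kpos - off
                if start0 < 0 or start0 + L > genome.length(contig):
                    continue
                candidates.add((contig, start0))
        for contig, start0 in candidates:
            mm = _hamming_le(
                query, genome.contigs[contig][start0 : start0 + L], max_mismatches
            )
            if mm is not None:
                key = (contig, start0 + 1, strand)
                if key not in hits or mm < hits[key]:
                    hits[key] = mm
    return HitList(
        oligo=oligo,
        hits=sorted(
            (Hit(c, s, st, mm) for (c, s, st), mm in hits.items()),
            key=lambda h: (h.contig, h.start, h.strand),
        ),
        max_mismatches=max_mismatches,
    )


def naive_scan(
    oligo: str, genome: GenomeRef, max_mismatches: int = DEFAULT_MAX_MISMATCHES
) -> HitList:
    """Exhaustive full-genome Hamming scan (audit mode; O(genome x oligo))."""
    L = len(oligo)
    rc = reverse_complement(oligo)
    hits = []
    for contig, seq in genome.contigs.items():
        for start0 in range(len(seq) - L + 1):
            window = seq[start0 : start0 + L]
            best = None
            for strand, query in (("+", oligo), ("-", rc)):
                mm = _hamming_le(query, window, max_mismatches)
                if mm is not None and (best is None or mm < best[1]):
                    best = (strand, mm)
            if best is not None:
                # report each strand hit separately, as scan() does
                for strand, query in (("+", oligo), ("-", rc)):
                    mm = _hamming_le(query, window, max_mismatches)
                    if mm is not None:
                        hits.append(Hit(contig, start0 + 1, strand, mm))
    return HitList(
        oligo=oligo,
        hits=sorted(hits, key=lambda h: (h.contig, h.start, h.strand)),
        max_mismatches=max_mismatches,
    )


@dataclass
class PairVerdict:
    pair_rank: int
    specific: bool
    forward_hits: int
    reverse_hits: int
    spurious_amplicons: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _plus_minus_combos(fhits, f_len, rhits, r_len, cap):
    """Convergent (plus-strand hit upstream of minus-strand hit) combos of
    one forward-oligo hit and one reverse-oligo hit within the distance cap."""
    out = []
    for h1 in fhits:
        for h2 in rhits:
            if h1.contig != h2.contig:
                continue
            for plus, minus, plen, mlen in (
                (h1, h2, f_len, r_len),
                (h2, h1, r_len, f_len),
            ):
                if plus.strand != "+" or minus.strand != "-":
                    continue
                left = plus.start
                right = minus.start + mlen - 1
                if left <= minus.start and 0 < right - left + 1 <= cap:
                    out.append(
                        {
                            "contig": h1.contig,
                            "start": left,
                            "end": right,
                            "size": right - left + 1,
                            "forward_hit": (h1.contig, h1.start, h1.strand, h1.mismatches),
                            "reverse_hit": (h2.contig, h2.start, h2.strand, h2.mismatches),
                        }
                    )
    return out


def specificity_report(
    pairs,
    intended_spans,
    index: GenomeIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    amplicon_cap: int = DEFAULT_AMPLICON_CAP,
) -> list[PairVerdict]:
    """Per-pair specificity verdicts.

    intended_spans: rank -> (forward GenomicSpan, reverse GenomicSpan) of
    the design locus; hit combinations reproducing the intended locus are
    not counted as spurious.  Secondary hits that cannot form a convergent
    product within the cap downgrade the verdict only to a warning.
    """
    verdicts = []
    for pair in pairs:
        fh = scan(pair.forward.sequence, index, max_mismatches)
        rh = scan(pair.reverse.sequence, index, max_mismatches)
        fspan, rspan = intended_spans[pair.rank]
        intended_starts = {
            (fspan.contig, b[0]) for b in fspan.blocks
        } | {(rspan.contig, b[0]) for b in rspan.blocks}
        combos = _plus_minus_combos(
            fh.hits, pair.forward.length, rh.hits, pair.reverse.length, amplicon_cap
        )
        spurious = [
            c
            for c in combos
            if not (
                (c["forward_hit"][0], c["forward_hit"][1]) in intended_starts
                and (c["reverse_hit"][0], c["reverse_hit"][1]) in intended_starts
            )
        ]
        warns = []
        if len(fh.hits) > 1 or len(rh.hits) > 1:
            if not spurious:
                warns.append(
                    "secondary hits present but no convergent pair within "
                    f"{amplicon_cap} bp"
                )
        verdicts.append(
            PairVerdict(
                pair_rank=pair.rank,
                specific=not spurious,
                forward_hits=len(fh.hits),
                reverse_hits=len(rh.hits),
                spurious_amplicons=spurious,
                warnings=warns,
            )
        )
    return verdicts
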