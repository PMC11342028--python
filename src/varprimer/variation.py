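"""Cohort variation annotation of primer binding sites.

For each designed oligo we walk its genomic footprint base by base (5'->3'
in oligo orientation) and, for a user-selected cohort of samples from the
VCF, compute the summed alternate allele frequency at every position: the
sum over all non-reference SNP alleles of alt_count / called_alleles, with
missing genotypes excluded from the denominator.  Sites absent from the VCF
are invariant (frequency 0).  Variants overlapping the last five 3' bases
are the high-risk class — mismatches there disrupt polymerase extension —
and drive the per-primer risk flags and the IUPAC degenerate redesign.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .coordinates import GenomicSpan, oligo_base_positions

__all__ = [
    "CohortQuery",
    "SiteRecord",
    "SiteFrequencyTrack",
    "DegeneratePrimer",
    "VariantTable",
    "select_cohort",
    "site_frequencies",
    "flag_risk",
    "degenerate",
]

THREE_PRIME_WINDOW = 5
DEFAULT_THRESHOLD = 0.05

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
IUPAC_EXPAND = {v: set(k) for k, v in IUPAC.items()}


@dataclass(frozen=True)
class CohortQuery:
    """AND-combined equality/membership clauses over sample-metadata
    columns, e.g. ``taxon=coluzzii,country=Ghana``.  An empty query selects
    every sample."""

    clauses: tuple[tuple[str, tuple[str, ...]], ...] = ()

    @classmethod
    def parse(cls, text: str) -> "CohortQuery":
        text = text.strip()
        if not text:
            return cls()
        clauses = []
        for part in text.split(","):
            m = re.fullmatch(r"\s*(\w+)\s*=\s*(.+?)\s*", part)
            if not m:
                raise ValueError(f"bad cohort clause {part!r}; expected col=value")
            col, val = m.group(1), m.group(2)
            clauses.append((col, tuple(v.strip() for v in val.split("|"))))
        return cls(tuple(clauses))


def select_cohort(metadata: pd.DataFrame, query: CohortQuery) -> list[str]:
    """Sample ids matching every clause of the query (all samples for an
    empty query).  Errors on unknown columns (listing the valid ones) and on
    an empty selection — a silently empty cohort would make every site look
    invariant."""
    if "sample_id" not in metadata.columns:
        raise ValueError("metadata must have a sample_id column")
    if metadata["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    mask = pd.Series(True, index=metadata.index)
    for col, values in query.clauses:
        if col not in metadata.columns:
            raise KeyError(
                f"unknown metadata column {col!r}; valid columns: "
                f"{sorted(metadata.columns)}"
            )
        mask &= metadata[col].astype(str).isin(values)
    ids = metadata.loc[mask, "sample_id"].tolist()
    if not ids:
        raise ValueError(f"cohort query selected no samples: {query.clauses}")
    return ids


@dataclass
class VariantTable:
    """In-memory view of a VCF: per (contig, pos) the SNP records
    (ref, alts, per-sample genotype allele indices) plus indel flags.

    Built once per run; desk-scale VCFs fit comfortably in memory, and a
    plain-text (uncompressed) VCF needs no index this way.
    """

    samples: list[str]
    snps: dict[tuple[str, int], list[tuple[str, list[str], list[tuple[int, int]]]]]
    indel_positions: set[tuple[str, int]]
    contigs: set[str]

    @classmethod
    def from_vcf(cls, vcf_path) -> "VariantTable":
        from cyvcf2 import VCF

        vcf = VCF(str(vcf_path), gts012=False)
        samples = list(vcf.samples)
        snps: dict = {}
        indels: set = set()
        contigs: set = set(vcf.seqnames)
        for var in vcf:
            contigs.add(var.CHROM)
            alts = [a for a in var.ALT if a not in (None, ".")]
            is_snp = len(var.REF) == 1 and alts and all(
                len(a) == 1 and a in "ACGT" for a in alts
            )
            gts = [(g[0], g[1]) for g in var.genotypes]
            key = (var.CHROM, var.POS)
            if is_snp:
                snps.setdefault(key, []).append((var.REF, alts, gts))
            else:
                for off in range(max(len(var.REF), 1)):
                    indels.add((var.CHROM, var.POS + off))
        vcf.close()
        return cls(samples=samples, snps=snps, indel_positions=indels, contigs=contigs)

    def sample_indices(self, sample_ids: list[str]) -> list[int]:
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in VCF: {missing[:5]}")
        return [pos[s] for s in sample_ids]


@dataclass(frozen=True)
class SiteRecord:
    """Per-base cohort variation at one oligo position."""

    oligo_index: int          # 0-based, 5'->3'
    genomic_position: int
    ref: str
    alt_freqs: tuple[tuple[str, float], ...]
    summed_alt_freq: float
    segregating: bool
    in_3prime_window: bool
    has_indel: bool = False
    all_missing: bool = False


@dataclass
class SiteFrequencyTrack:
    """Ordered per-base variation track for one oligo (5'->3')."""

    oligo_name: str
    sequence: str
    span: GenomicSpan
    orientation: str
    cohort_size: int
    sites: list[SiteRecord] = field(default_factory=list)

    @property
    def max_freq(self) -> float:
        return max((s.summed_alt_freq for s in self.sites), default=0.0)

    @property
    def any_segregating(self) -> bool:
        return any(s.segregating for s in self.sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "oligo_index": [s.oligo_index for s in self.sites],
                "base": list(self.sequence),
                "contig": self.span.contig,
                "position": [s.genomic_position for s in self.sites],
                "ref": [s.ref for s in self.sites],
                "summed_alt_freq": [s.summed_alt_freq for s in self.sites],
                "segregating": [s.segregating for s in self.sites],
                "in_3prime_window": [s.in_3prime_window for s in self.sites],
                "has_indel": [s.has_indel for s in self.sites],
            }
        )


def _site_alt_freqs(
    records, cohort_idx: list[int]
) -> tuple[list[tuple[str, float]], bool]:
    """Per-alt frequencies over called cohort alleles; True flag when every
    cohort genotype is missing at a covered record."""
    freqs: list[tuple[str, float]] = []
    all_missing = False
    for ref, alts, gts in records:
        counts = {i + 1: 0 for i in range(len(alts))}
        called = 0
        for si in cohort_idx:
            for allele in gts[si]:
                if allele < 0:
                    continue
                called += 1
                if allele in counts:
                    counts[allele] += 1
        if called == 0:
            all_missing = True
            continue
        for i, alt in enumerate(alts):
            freqs.append((alt, counts[i + 1] / called))
    return freqs, all_missing


def site_frequencies(
    span: GenomicSpan,
    variants: VariantTable,
    cohort_ids: list[str],
    sequence: str,
    orientation: str = "forward",
    oligo_name: str = "oligo",
    reference_bases: list[str] | None = None,
) -> SiteFrequencyTrack:
    """Summed alternate allele frequency at every base of an oligo's
    genomic span, in oligo 5'->3' order.

    Positions absent from the VCF get frequency 0 / segregating False.
    Multiallelic records sum over all alts (capped at 1).  A site where all
    cohort genotypes are missing is flagged and treated as frequency 0 with
    a warning.
    """
    if span.contig not in variants.contigs:
        raise ValueError(
            f"contig {span.contig!r} absent from VCF (has {sorted(variants.contigs)})"
        )
    cohort_idx = variants.sample_indices(cohort_ids)
    positions = oligo_base_positions(span, orientation)
    if len(positions) != len(sequence):
        raise ValueError("span length does not match oligo length")
    n = len(positions)
    sites: list[SiteRecord] = []
    for i, gpos in enumerate(positions):
        key = (span.contig, gpos)
        records = variants.snps.get(key, [])
        freqs, all_missing = _site_alt_freqs(records, cohort_idx)
        if all_missing:
            warnings.warn(
                f"{oligo_name}: all cohort genotypes missing at "
                f"{span.contig}:{gpos}; frequency undefined, treated as 0",
                stacklevel=2,
            )
        summed = min(sum(f for _, f in freqs), 1.0)
        ref = records[0][0] if records else (
            reference_bases[i] if reference_bases else "."
        )
        sites.append(
            SiteRecord(
                oligo_index=i,
                genomic_position=gpos,
                ref=ref,
                alt_freqs=tuple(freqs),
                summed_alt_freq=summed,
                segregating=summed > 0,
                in_3prime_window=i >= n - THREE_PRIME_WINDOW,
                has_indel=key in variants.indel_positions,
                all_missing=all_missing,
            )
        )
    return SiteFrequencyTrack(
        oligo_name=oligo_name,
        sequence=sequence,
        span=span,
        orientation=orientation,
        cohort_size=len(cohort_ids),
        sites=sites,
    )


def flag_risk(
    tracks: list[SiteFrequencyTrack], threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Per-oligo risk flags, best-first.

    has_3prime_snp: a segregating site with summed frequency >= threshold
    within the last five 3' bases.  Oligos sort by (has_3prime_snp,
    max_freq) ascending so the safest binding sites come first.
    """
    rows = []
    for t in tracks:
        has3 = any(
            s.segregating and s.summed_alt_freq >= threshold and s.in_3prime_window
            for s in t.sites
        )
        rows.append(
            {
                "oligo": t.oligo_name,
                "any_segregating": t.any_segregating,
                "max_freq": t.max_freq,
                "n_segregating": sum(s.segregating for s in t.sites),
                "has_3prime_snp": has3,
                "has_indel": any(s.has_indel for s in t.sites),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["has_3prime_snp", "max_freq", "oligo"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass(frozen=True)
class DegeneratePrimer:
    """IUPAC-degenerate redesign of one oligo."""

    sequence: str
    degeneracy: int
    substituted_positions: tuple[int, ...]
    flagged_indel_positions: tuple[int, ...] = ()

    def expansions(self) -> list[str]:
        seqs = [""]
        for ch in self.sequence:
            seqs = [s + b for s in seqs for b in sorted(IUPAC_EXPAND[ch])]
        return seqs


def degenerate(
    seq: str, track: SiteFrequencyTrack, threshold: float = DEFAULT_THRESHOLD
) -> DegeneratePrimer:
    """Replace each oligo base carrying a qualifying SNP (summed alt
    frequency >= threshold) with the IUPAC code covering the oligo base plus
    the qualifying alternate alleles; degeneracy is the product of per-base
    allele counts.  Indel positions are flagged, never degenerated (IUPAC
    cannot encode length variants)."""
    if len(seq) != len(track.sites):
        raise ValueError("track not aligned to sequence")
    out = []
    subbed = []
    indels = []
    degeneracy = 1
    # an oligo base equals the genomic-strand allele only when template
    # strand and primer orientation agree; otherwise it is the complement
    needs_comp = (track.span.strand == "+") != (track.orientation == "forward")
    comp = str.maketrans("ACGT", "TGCA")
    for i, (base, site) in enumerate(zip(seq, track.sites)):
        if site.has_indel:
            indels.append(i)
        qualifying = {
            alt for alt, f in site.alt_freqs if f >= threshold and f > 0
        }
        if not qualifying:
            out.append(base)
            continue
        if needs_comp:
            alleles = frozenset({base} | {a.translate(comp) for a in qualifying})
        else:
            alleles = frozenset({base} | qualifying)
        out.append(IUPAC[alleles])
        subbed.append(i)
        degeneracy *= len(alleles)
    return DegeneratePrimer(
        sequence="".join(out),
        degeneracy=degeneracy,
        substituted_positions=tuple(subbed),
        flagged_indel_positions=tuple(indels),
    )


def plot_track(track: SiteFrequencyTrack, path) -> None:
    """Static per-oligo frequency plot: one circle per base along the oligo
    5'->3', filled when segregating, y = summed alternate allele
    frequency."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(track.sequence) * 0.25), 2.5))
    xs = list(range(len(track.sequence)))
    for s in track.sites:
        if s.segregating:
            ax.plot(s.oligo_index, s.summed_alt_freq, "o", color="tab:blue")
        else:
            ax.plot(s.oligo_index, 0.0, "o", mfc="none", color="0.6")
    ax.set_xticks(xs)
    ax.set_xticklabels(list(track.sequence), fontsize=7)
    ax.axvspan(len(xs) - THREE_PRIME_WINDOW - 0.5, len(xs) - 0.5,
               color="tab:red", alpha=0.08)
    ax.set_ylim(-0.05, 1.05)
    ax.set_ylabel("summed alt freq")
    ax.set_title(f"{track.oligo_name}  {track.span.display}  (n={track.cohort_size})",
                 fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
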