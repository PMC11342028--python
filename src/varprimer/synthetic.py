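"""Deterministic synthetic data: a toy genome, gene models, a cohort VCF
and sample metadata, for end-to-end exercise of the design pipeline with no
external downloads.

The generator emulates the shape of real inputs — multi-exon genes on both
strands, cohort SNPs at controlled frequencies, duplicated segments and
planted oligo copies for specificity testing — not real nucleotide
composition or population structure.  Genotypes at planted SNPs are
*allocated*, not sampled: the alternate allele count is round(freq x 2n),
assigned to the first samples of the target cohort as homozygotes then one
heterozygote, so recovered frequencies are exact and assertions against the
manifest can be exact too.  Everything is a pure function of the manifest
(seed included): regeneration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .thermo import reverse_complement

__all__ = [
    "GeneSpec",
    "SNPSpec",
    "DuplicationSpec",
    "OligoCopySpec",
    "CohortSpec",
    "FixtureManifest",
    "FixtureFiles",
    "generate",
    "default_manifest",
    "random_manifest",
]

_BASES = np.array(list("ACGT"))
_BG_P = np.array([0.275, 0.225, 0.225, 0.275])  # GC ~ 0.45
_NEXT_ALT = {"A": "G", "G": "A", "C": "T", "T": "C"}  # transition partner


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    contig: str
    strand: str
    start: int                       # genomic start of exon 1 hull, 1-based
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]

    def exon_intervals(self) -> list[tuple[int, int]]:
        """Genomic (start, end) per exon in ascending coordinate order."""
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError(f"{self.gene_id}: need n_exons - 1 intron lengths")
        out = []
        pos = self.start
        for i, ln in enumerate(self.exon_lengths):
            out.append((pos, pos + ln - 1))
            pos += ln
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        return out

    @property
    def end(self) -> int:
        return self.exon_intervals()[-1][1]

    @property
    def transcript_id(self) -> str:
        return f"{self.gene_id}-RA"


@dataclass(frozen=True)
class SNPSpec:
    contig: str
    position: int
    target_freq: tuple[float, ...]           # one entry per alt allele
    alts: tuple[str, ...] = ()               # derived from ref when empty
    cohort_column: str | None = None         # restrict carriers to a cohort
    cohort_value: str | None = None


@dataclass(frozen=True)
class DuplicationSpec:
    contig: str
    start: int
    length: int
    dest_contig: str
    dest_start: int


@dataclass(frozen=True)
class OligoCopySpec:
    sequence: str
    sites: tuple[tuple[str, int, str], ...]  # (contig, 1-based pos, strand)


@dataclass(frozen=True)
class CohortSpec:
    n: int
    taxon: str
    country: str
    year: int
    location: str
    sample_set: str


@dataclass(frozen=True)
class FixtureManifest:
    seed: int
    contig_lengths: dict[str, int]
    genes: tuple[GeneSpec, ...] = ()
    snps: tuple[SNPSpec, ...] = ()
    duplications: tuple[DuplicationSpec, ...] = ()
    oligo_copies: tuple[OligoCopySpec, ...] = ()
    cohorts: tuple[CohortSpec, ...] = (
        CohortSpec(30, "coluzzii", "Ghana", 2019, "Obuasi", "SET-A"),
        CohortSpec(70, "gambiae", "Ghana", 2019, "Madina", "SET-A"),
    )

    @property
    def n_samples(self) -> int:
        return sum(c.n for c in self.cohorts)

    def sample_rows(self) -> list[dict]:
        rows = []
        i = 0
        for c in self.cohorts:
            for _ in range(c.n):
                i += 1
                rows.append(
                    {
                        "sample_id": f"S{i:04d}",
                        "taxon": c.taxon,
                        "country": c.country,
                        "year": c.year,
                        "location": c.location,
                        "sample_set": c.sample_set,
                    }
                )
        return rows


@dataclass(frozen=True)
class FixtureFiles:
    fasta: Path
    gff3: Path
    vcf: Path
    metadata: Path
    manifest: Path


def _build_contigs(manifest: FixtureManifest) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(manifest.seed)
    contigs = {
        name: rng.choice(_BASES, size=length, p=_BG_P)
        for name, length in manifest.contig_lengths.items()
    }
    occupied: dict[str, set[int]] = {c: set() for c in contigs}

    def claim(contig, start0, length, what):
        span = range(start0, start0 + length)
        if start0 < 0 or start0 + length > len(contigs[contig]):
            raise ValueError(f"{what}: outside contig {contig}")
        clash = occupied[contig].intersection(span)
        if clash:
            raise ValueError(f"{what}: collides with a planted feature on {contig}")
        occupied[contig].update(span)

    for oc in manifest.oligo_copies:
        for contig, pos, strand in oc.sites:
            seq = oc.sequence if strand == "+" else reverse_complement(oc.sequence)
            claim(contig, pos - 1, len(seq), f"oligo copy at {contig}:{pos}")
            contigs[contig][pos - 1 : pos - 1 + len(seq)] = list(seq)
    for dup in manifest.duplications:
        claim(dup.dest_contig, dup.dest_start - 1, dup.length,
              f"duplication into {dup.dest_contig}:{dup.dest_start}")
        src = contigs[dup.contig][dup.start - 1 : dup.start - 1 + dup.length]
        contigs[dup.dest_contig][dup.dest_start - 1 : dup.dest_start - 1 + dup.length] = src
    return contigs


def _snp_alleles(snp: SNPSpec, ref: str) -> tuple[str, ...]:
    if snp.alts:
        if ref in snp.alts:
            raise ValueError(f"SNP at {snp.contig}:{snp.position}: alt equals ref")
        return snp.alts
    # transition partner first, then remaining bases in alphabetical order
    pool = [_NEXT_ALT[ref]] + [b for b in "ACGT" if b not in (ref, _NEXT_ALT[ref])]
    return tuple(pool[: len(snp.target_freq)])


def _allocate_genotypes(
    snp: SNPSpec, manifest: FixtureManifest, sample_rows: list[dict]
) -> list[tuple[int, int]]:
    """Deterministic genotype allocation hitting target allele counts.

    Within the target cohort (all samples when unrestricted), each alt
    allele a with target frequency f gets round(f * 2n) copies laid down as
    homozygotes first, one heterozygote for an odd remainder."""
    if snp.cohort_column is None:
        target = list(range(len(sample_rows)))
    else:
        target = [
            i for i, r in enumerate(sample_rows)
            if str(r[snp.cohort_column]) == snp.cohort_value
        ]
        if not target:
            raise ValueError(
                f"SNP cohort {snp.cohort_column}={snp.cohort_value} matches no sample"
            )
    gts = [(0, 0)] * len(sample_rows)
    cursor = 0
    for alt_idx, freq in enumerate(snp.target_freq, start=1):
        want = round(freq * 2 * len(target))
        while want >= 2 and cursor < len(target):
            gts[target[cursor]] = (alt_idx, alt_idx)
            cursor += 1
            want -= 2
        if want == 1:
            if cursor >= len(target):
                raise ValueError("allele count exceeds cohort capacity")
            gts[target[cursor]] = (0, alt_idx)
            cursor += 1
            want = 0
        if want > 0:
            raise ValueError("allele count exceeds cohort capacity")
    return gts


def generate(manifest: FixtureManifest, outdir) -> FixtureFiles:
    """Emit FASTA, GFF3, VCF (4.2), metadata TSV and a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = _build_contigs(manifest)

    for gene in manifest.genes:
        if gene.end > manifest.contig_lengths[gene.contig]:
            raise ValueError(f"{gene.gene_id} extends past contig {gene.contig}")

    snp_keys = [(s.contig, s.position) for s in manifest.snps]
    if len(set(snp_keys)) != len(snp_keys):
        raise ValueError("two SNPs planted at the same position")

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for name in manifest.contig_lengths:
            fh.write(f">{name}\n")
            seq = "".join(contigs[name])
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    gff3 = outdir / "genes.gff3"
    with open(gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, ln in manifest.contig_lengths.items():
            fh.write(f"##sequence-region {name} 1 {ln}\n")
        for gene in manifest.genes:
            exons = gene.exon_intervals()
            gs, ge = exons[0][0], exons[-1][1]
            tid = gene.transcript_id
            fh.write(
                f"{gene.contig}\tsynthetic\tgene\t{gs}\t{ge}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            fh.write(
                f"{gene.contig}\tsynthetic\tmRNA\t{gs}\t{ge}\t.\t{gene.strand}\t.\t"
                f"ID={tid};Parent={gene.gene_id}\n"
            )
            for j, (es, ee) in enumerate(exons, start=1):
                fh.write(
                    f"{gene.contig}\tsynthetic\texon\t{es}\t{ee}\t.\t{gene.strand}\t.\t"
                    f"ID={tid}-E{j};Parent={tid}\n"
                )

    sample_rows = manifest.sample_rows()
    metadata = outdir / "samples.tsv"
    with open(metadata, "w") as fh:
        cols = ["sample_id", "taxon", "country", "year", "location", "sample_set"]
        fh.write("\t".join(cols) + "\n")
        for r in sample_rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")

    vcf = outdir / "cohort.vcf"
    snp_manifest = []
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=varprimer-synthetic\n")
        for name, ln in manifest.contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(r["sample_id"] for r in sample_rows)
            + "\n"
        )
        order = {c: i for i, c in enumerate(manifest.contig_lengths)}
        for snp in sorted(manifest.snps, key=lambda s: (order[s.contig], s.position)):
            ref = str(contigs[snp.contig][snp.position - 1])
            alts = _snp_alleles(snp, ref)
            gts = _allocate_genotypes(snp, manifest, sample_rows)
            gt_str = "\t".join(f"{min(a, b)}/{max(a, b)}" for a, b in gts)
            fh.write(
                f"{snp.contig}\t{snp.position}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t"
                f".\tGT\t{gt_str}\n"
            )
            counts = [
                sum(1 for a, b in gts for al in (a, b) if al == k)
                for k in range(1, len(alts) + 1)
            ]
            snp_manifest.append(
                {
                    "contig": snp.contig,
                    "position": snp.position,
                    "ref": ref,
                    "alts": list(alts),
                    "target_freq": list(snp.target_freq),
                    "allele_counts": counts,
                    "total_alleles": 2 * len(sample_rows),
                    "cohort_column": snp.cohort_column,
                    "cohort_value": snp.cohort_value,
                }
            )

    manifest_path = outdir / "manifest.json"
    doc = dataclasses.asdict(manifest)
    doc["derived"] = {
        "snps": snp_manifest,
        "transcripts": {
            g.transcript_id: {
                "contig": g.contig,
                "strand": g.strand,
                "exons": [list(e) for e in g.exon_intervals()],
                "spliced_length": sum(g.exon_lengths),
            }
            for g in manifest.genes
        },
        "samples": sample_rows,
    }
    with open(manifest_path, "w") as fh:
        json.dump(doc, fh, indent=1, default=list)

    return FixtureFiles(
        fasta=fasta, gff3=gff3, vcf=vcf, metadata=metadata, manifest=manifest_path
    )


def default_manifest(seed: int = 0) -> FixtureManifest:
    """The standard worked-example fixture: three contigs, multi-exon genes
    on both strands, cohort SNPs in and around the first gene, one
    duplicated segment and one twice-planted oligo."""
    genes = (
        GeneSpec("G1", "chr1", "+", 2001, (120, 80, 200), (400, 350)),
        GeneSpec("G2", "chr1", "-", 6001, (150, 90, 120, 60), (200, 300, 250)),
        GeneSpec("G3", "chr2", "+", 3001, (500,), ()),
        GeneSpec("G4", "chr2", "-", 6001, (100, 100), (500,)),
    )
    snps = (
        SNPSpec("chr1", 2030, (0.10,)),
        SNPSpec("chr1", 2118, (0.30,)),                      # near junction 1
        SNPSpec("chr1", 2521, (0.05, 0.15)),                 # multiallelic, exon 2
        SNPSpec("chr1", 2890, (0.50,), cohort_column="taxon", cohort_value="gambiae"),
        SNPSpec("chr1", 4000, (0.20,)),                      # intergenic
        SNPSpec("chr1", 6050, (0.08,)),
        SNPSpec("chr2", 3100, (0.40,)),
        SNPSpec("chr2", 3101, (0.02,)),
    )
    dups = (DuplicationSpec("chr2", 3001, 700, "chr3", 4001),)
    return FixtureManifest(
        seed=seed,
        contig_lengths={"chr1": 12000, "chr2": 10000, "chr3": 8000},
        genes=genes,
        snps=snps,
        duplications=dups,
    )


def random_manifest(seed: int, n_samples: int = 20) -> FixtureManifest:
    """A small randomised fixture (one multi-exon gene, random SNPs) for
    property tests sweeping many seeds."""
    rng = np.random.default_rng(seed)
    n_exons = int(rng.integers(2, 6))
    exon_lengths = tuple(int(rng.integers(80, 260)) for _ in range(n_exons))
    intron_lengths = tuple(int(rng.integers(60, 400)) for _ in range(n_exons - 1))
    strand = "+" if rng.random() < 0.5 else "-"
    gene_start = 501
    gene = GeneSpec("GX", "chr1", strand, gene_start, exon_lengths, intron_lengths)
    contig_len = gene.end + 500
    n_snps = int(rng.integers(2, 8))
    positions = rng.choice(
        np.arange(gene_start, gene.end), size=n_snps, replace=False
    )
    freq_grid = np.arange(1, 2 * n_samples + 1) / (2 * n_samples)
    snps = tuple(
        SNPSpec("chr1", int(p), (float(rng.choice(freq_grid[:n_samples])),))
        for p in sorted(positions)
    )
    cohorts = (
        CohortSpec(n_samples // 2, "coluzzii", "Ghana", 2019, "Obuasi", "SET-A"),
        CohortSpec(n_samples - n_samples // 2, "gambiae", "Benin", 2020, "Cotonou", "SET-B"),
    )
    return FixtureManifest(
        seed=seed,
        contig_lengths={"chr1": int(contig_len)},
        genes=(gene,),
        snps=snps,
        cohorts=cohorts,
    )
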