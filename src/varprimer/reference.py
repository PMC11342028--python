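"""Reference genome and annotation handling.

Reads a FASTA genome and a GFF3 annotation, builds strand-aware transcript
models, and extracts the design templates: a genomic window around a target
position (gDNA / probe assays) or the spliced cDNA of a transcript with the
exon-exon junction offsets recorded (cDNA assays).

Coordinates are 1-based inclusive throughout, matching GFF3 and the
``contig:start-end`` style used in design reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

from .thermo import reverse_complement

__all__ = [
    "GenomeRef",
    "TranscriptModel",
    "Template",
    "read_genome",
    "load_transcript",
    "extract_template",
]

_IUPAC_DNA = set("ACGTNRYSWKMBDHV")

DEFAULT_FLANK = 500


@dataclass
class GenomeRef:
    """In-memory reference genome.

    contigs : contig name -> uppercase sequence (ACGTN + rare IUPAC codes)
    masks   : contig name -> sorted list of (start, end) 1-based inclusive
              intervals that were soft-masked (lowercase) in the input
    """

    contigs: dict[str, str]
    masks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """1-based inclusive slice."""
        return self.contigs[contig][start - 1 : end]

    def masked_fraction(self, contig: str, start: int, end: int) -> float:
        """Fraction of [start, end] that was soft-masked in the input."""
        covered = 0
        for ms, me in self.masks.get(contig, ()):
            lo, hi = max(ms, start), min(me, end)
            if lo <= hi:
                covered += hi - lo + 1
        return covered / (end - start + 1)


@dataclass
class TranscriptModel:
    """Exon structure of one mRNA.

    exons are (start, end) 1-based inclusive genomic intervals listed in
    transcription order: ascending genomic coordinate on '+', descending
    on '-'.
    """

    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_present: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 >= s2:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcription order"
            )

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    @property
    def spliced_length(self) -> int:
        return sum(self.exon_lengths)

    def spliced_sequence(self, genome: GenomeRef) -> str:
        parts = []
        for s, e in self.exons:
            piece = genome.fetch(self.contig, s, e)
            parts.append(piece if self.strand == "+" else reverse_complement(piece))
        return "".join(parts)


@dataclass
class Template:
    """A design template: the sequence primers are enumerated on.

    kind             : 'gDNA' | 'cDNA' | 'probe_window'
    contig           : source contig
    window_start     : genomic coordinate of template position 0 (gDNA modes)
    transcript       : source model (cDNA mode)
    junction_offsets : template positions p such that an exon-exon boundary
                       lies immediately after template base p-1 (1-based
                       cumulative exon lengths; empty for gDNA and
                       single-exon transcripts)
    """

    sequence: str
    kind: str
    contig: str
    window_start: int | None = None
    transcript: TranscriptModel | None = None
    junction_offsets: list[int] = field(default_factory=list)
    masked_fraction: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if any(not 1 <= j <= n - 1 for j in self.junction_offsets):
            raise ValueError("junction offset outside (0, len)")
        if sorted(self.junction_offsets) != self.junction_offsets:
            raise ValueError("junction offsets not increasing")

    def __len__(self) -> int:
        return len(self.sequence)


def read_genome(fasta_path) -> GenomeRef:
    """Load a FASTA genome, uppercasing sequence and recording soft-masked
    (lowercase) runs per contig.

    Raises on duplicate contig names and on non-IUPAC characters, naming the
    record and 1-based offset of the first offender.
    """
    contigs: dict[str, str] = {}
    masks: dict[str, list[tuple[int, int]]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {fasta_path}")
        raw = str(rec.seq)
        if not raw:
            raise ValueError(f"contig {rec.id!r} is empty")
        seq = raw.upper()
        for i, ch in enumerate(seq):
            if ch not in _IUPAC_DNA:
                raise ValueError(
                    f"non-IUPAC character {ch!r} in record {rec.id!r} "
                    f"at offset {i + 1}"
                )
        runs: list[tuple[int, int]] = []
        start = None
        for i, ch in enumerate(raw):
            if ch.islower():
                if start is None:
                    start = i + 1
            elif start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(raw)))
        contigs[rec.id] = seq
        if runs:
            masks[rec.id] = runs
    if not contigs:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return GenomeRef(contigs=contigs, masks=masks)


def _open_gff(gff3_path) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )


def available_transcripts(gff3_path) -> list[str]:
    db = _open_gff(gff3_path)
    ids = []
    for ftype in ("mRNA", "transcript"):
        ids.extend(f.id for f in db.features_of_type(ftype))
    return sorted(set(ids))


def load_transcript(gff3_path, genome: GenomeRef, transcript_id: str) -> TranscriptModel:
    """Build a TranscriptModel for ``transcript_id`` from a GFF3 file.

    The transcript must be an mRNA/transcript feature with >=1 exon child;
    exons are returned in transcription order and validated against contig
    bounds.
    """
    db = _open_gff(gff3_path)
    try:
        feat = db[transcript_id]
    except gffutils.FeatureNotFoundError:
        avail = []
        for ftype in ("mRNA", "transcript"):
            avail.extend(f.id for f in db.features_of_type(ftype))
        raise KeyError(
            f"transcript {transcript_id!r} not found; available: {sorted(set(avail))}"
        ) from None
    if feat.featuretype not in ("mRNA", "transcript"):
        raise ValueError(
            f"{transcript_id!r} is a {feat.featuretype}, not an mRNA/transcript"
        )
    exons = [(c.start, c.end) for c in db.children(feat, featuretype="exon")]
    if not exons:
        raise ValueError(f"transcript {transcript_id!r} has no exon children")
    cds = any(True for _ in db.children(feat, featuretype="CDS"))
    exons.sort()
    if feat.strand == "-":
        exons = exons[::-1]
    if feat.seqid not in genome.contigs:
        raise ValueError(f"contig {feat.seqid!r} not in genome")
    clen = genome.length(feat.seqid)
    for s, e in exons:
        if not (1 <= s <= e <= clen):
            raise ValueError(
                f"exon {s}-{e} of {transcript_id!r} outside contig "
                f"{feat.seqid!r} (length {clen})"
            )
    return TranscriptModel(
        transcript_id=transcript_id,
        contig=feat.seqid,
        strand=feat.strand,
        exons=exons,
        cds_present=cds,
    )


def parse_target(target: str) -> tuple[str, int]:
    """Parse a 'contig:position' gDNA target."""
    try:
        contig, pos = target.rsplit(":", 1)
        return contig, int(pos.replace(",", ""))
    except ValueError:
        raise ValueError(f"bad target {target!r}; expected 'contig:position'") from None


def extract_template(
    target: str | None,
    mode: str,
    genome: GenomeRef,
    transcript: TranscriptModel | None = None,
    flank: int = DEFAULT_FLANK,
) -> Template:
    """Build the design template.

    gDNA / probe_window mode: the genomic window [position - flank,
    position + flank] around ``target`` ('contig:position'), clipped to the
    contig with a warning.  cDNA mode: the spliced exon sequence of
    ``transcript`` with junction offsets at cumulative exon-length
    boundaries.
    """
    if mode == "cDNA":
        if transcript is None:
            raise ValueError("cDNA mode requires a transcript model")
        seq = transcript.spliced_sequence(genome)
        offsets = []
        cum = 0
        for ln in transcript.exon_lengths[:-1]:
            cum += ln
            offsets.append(cum)
        mstart = min(s for s, _ in transcript.exons)
        mend = max(e for _, e in transcript.exons)
        return Template(
            sequence=seq,
            kind="cDNA",
            contig=transcript.contig,
            transcript=transcript,
            junction_offsets=offsets,
            masked_fraction=genome.masked_fraction(transcript.contig, mstart, mend),
        )
    if mode not in ("gDNA", "probe_window"):
        raise ValueError(f"unknown template mode {mode!r}")
    if flank <= 0:
        raise ValueError("flank must be positive")
    contig, pos = parse_target(target)
    if contig not in genome.contigs:
        raise ValueError(f"contig {contig!r} not in genome")
    clen = genome.length(contig)
    if not 1 <= pos <= clen:
        raise ValueError(f"position {pos} outside contig {contig!r} (length {clen})")
    start, end = pos - flank, pos + flank
    if start < 1 or end > clen:
        start, end = max(1, start), min(clen, end)
        warnings.warn(
            f"template window clipped to {contig}:{start}-{end}", stacklevel=2
        )
    return Template(
        sequence=genome.fetch(contig, start, end),
        kind=mode,
        contig=contig,
        window_start=start,
        masked_fraction=genome.masked_fraction(contig, start, end),
    )
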