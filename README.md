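# varprimer

Variation-aware PCR primer and probe design for organisms with dense
population-genomic variation data, such as the major malaria vectors
*Anopheles gambiae s.l.* and *An. funestus*, where a segregating SNP occurs
every couple of accessible bases. SNPs under a primer destabilise the
primer–template duplex; under the 3'-terminal five bases they disrupt
polymerase extension outright, producing null alleles (allelic dropout) or
allele-biased amplification that standard genotyping cannot detect.

varprimer designs oligos against a **local** reference genome (FASTA),
annotation (GFF3) and cohort VCF, then tells you exactly which candidate
binding sites segregate in the cohort you care about:

- **gDNA primers, cDNA primers and hybridisation probes.** cDNA pairs place
  at least one mate across an exon–exon junction (where the transcript has
  one), so genomic DNA in the sample cannot amplify.
- **Per-base cohort allele frequencies** under every oligo: the summed
  alternate allele frequency at each position, for any cohort selected by
  metadata query (`taxon=coluzzii,country=Ghana`), with missing genotypes
  excluded from the denominator.
- **3'-end risk flags** and **IUPAC-degenerate redesigns** for oligos whose
  binding sites segregate above a frequency threshold.
- **Genome specificity**: a seed-and-extend Hamming scan of the reference
  flags primer pairs whose secondary hits could form a spurious amplicon.

## The core model

Candidate oligos are scored with nearest-neighbor duplex thermodynamics
(unified NN parameters):

    Tm = ΔH° / (ΔS°_salt + R ln(C_T/4)) − 273.15

with ΔH°, ΔS° summed over dinucleotide stacks plus initiation/terminal
corrections, the entropic salt correction ΔS°_salt = ΔS° + 0.368 (N−1)
ln[Na⁺]_eff, and the divalent conversion [Na⁺]_eff = [Na⁺] + 120 √([Mg²⁺] −
[dNTP]) (mM). Defaults: 50 mM monovalent, 1.5 mM Mg²⁺, 0.6 mM dNTP, 50 nM
oligo — the conventions of the standard PCR design stacks, so reported Tm
values match what Primer3-based tools print for the same oligo.

Surviving candidates are ranked by a weighted deviation-from-optimum
penalty (Tm, length, GC, self-complementarity, 3'-end stability); pairs add
a Tm-mismatch term. Ties break deterministically, so a run is byte-for-byte
reproducible.

## Worked example

Everything runs on a bundled synthetic fixture (no downloads):

```
varprimer fixtures generate --seed 1 --out fx
varprimer design --fasta fx/genome.fa --gff3 fx/genes.gff3 \
    --vcf fx/cohort.vcf --metadata fx/samples.tsv \
    --target G1-RA --assay cDNA_primers --n-pairs 3 \
    --cohort "taxon=coluzzii" --out run
```

`run/primers.tsv` (abridged):

```
pair  forward_sequence      reverse_sequence          forward_tm  reverse_tm  product_size_bp  forward_genomic_span  reverse_genomic_span  specific  reverse_max_alt_freq
0     TATGAGAACGGGACGCCAAT  CGGAGGATTTAAGTGGAGAGTTTC  59.17       59.13       75               chr1:2066-2085        chr1:2117-2540        True      1.0
1     ATATGAGAACGGGACGCCAA  CGGAGGATTTAAGTGGAGAGTTTC  59.17       59.13       76               chr1:2065-2084        chr1:2117-2540        True      1.0
2     GATATGAGAACGGGACGCCA  CGGAGGATTTAAGTGGAGAGTTTC  59.61       59.13       77               chr1:2064-2083        chr1:2117-2540        True      1.0
```

Reading pair 0: the 24-nt reverse primer spans the exon-1/exon-2 junction —
its genomic span `chr1:2117-2540` (424 bp) is far longer than the oligo
because the intron sits between its two genomic blocks, which is exactly
what blocks gDNA amplification. The product (75 bp) is inside the requested
60–120 bp range, and both oligos map to a unique genomic locus. But in the
*coluzzii* cohort this binding site segregates at frequency 1.0
(`reverse_max_alt_freq`), including inside the 3'-terminal window, so
`run/risk.tsv` flags it:

```
oligo          any_segregating  max_freq  n_segregating  has_3prime_snp
pair0_forward  False            0.0       0              False
pair0_reverse  True             1.0       2              True
```

and `run/candidates.json` proposes the degenerate rescue
`CGGAGGATTTAAGTGGAGADTTYC` (degeneracy 6): `D` covers a triallelic site,
`Y` the junction-adjacent SNP, both complemented into the primer's reading
strand. Rerun with `--cohort "taxon=gambiae"` and the same site is
invariant — the point of designing against the cohort you will assay.

Per-oligo frequency plots (one circle per base, filled when segregating,
3'-window shaded) land in `run/tracks/`, the primer-vs-exon layout in
`run/layout.svg`/`layout.json`, and run statistics (per-filter kill counts
for troubleshooting) in `run/candidates.json`.

A pre-existing primer list can be audited without redesigning:
`varprimer check --primers my_primers.tsv --fasta fx/genome.fa`.

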