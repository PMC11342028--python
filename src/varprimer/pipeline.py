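"""One-shot design workflow: template extraction -> candidate design ->
genomic mapping -> cohort variation annotation -> specificity screen ->
report bundle.

This is the library form of the command-line ``design`` run; each stage is
also usable on its own (the step-wise mode).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import coordinates, design, reference, specificity, variation
from .design import DesignParams, PrimerPair
from .reference import GenomeRef, Template
from .variation import CohortQuery

logger = logging.getLogger("varprimer")

__all__ = ["RunConfig", "DesignBundle", "run_design", "write_bundle"]


@dataclass
class RunConfig:
    fasta: str
    target: str
    assay_type: str = "gDNA_primers"
    gff3: str | None = None
    vcf: str | None = None
    metadata: str | None = None
    cohort: CohortQuery = field(default_factory=CohortQuery)
    params: DesignParams | None = None
    flank: int = reference.DEFAULT_FLANK
    risk_threshold: float = variation.DEFAULT_THRESHOLD
    max_mismatches: int = specificity.DEFAULT_MAX_MISMATCHES
    outdir: str | None = None
    seed: int = 0

    def resolved_params(self) -> DesignParams:
        if self.params is not None:
            return dataclasses.replace(self.params, assay_type=self.assay_type)
        return DesignParams(assay_type=self.assay_type)


@dataclass
class DesignBundle:
    config: RunConfig
    template: Template
    pairs: list[PrimerPair]
    spans: dict[tuple[int, str], coordinates.GenomicSpan]
    tracks: dict[tuple[int, str], variation.SiteFrequencyTrack]
    risk: pd.DataFrame | None
    degenerates: dict[tuple[int, str], variation.DegeneratePrimer]
    verdicts: list[specificity.PairVerdict]
    layout: dict
    stats: dict

    def oligo_roles(self, pair: PrimerPair):
        for role in ("forward", "reverse", "probe"):
            cand = getattr(pair, role)
            if cand is not None:
                yield role, cand


def _design_pairs(template: Template, params: DesignParams) -> tuple[list[PrimerPair], dict]:
    stats: dict = {}
    fwd = design.enumerate_candidates(template, params, "forward")
    rev = design.enumerate_candidates(template, params, "reverse")
    stats["forward_candidates"] = len(fwd)
    stats["reverse_candidates"] = len(rev)
    pairs = design.pair_candidates(fwd, rev, params, template)
    if params.wants_probe:
        out = []
        for p in pairs:
            probe = design.design_probe(template, params, p)
            out.append(dataclasses.replace(p, probe=probe))
            if probe is None:
                logger.warning("pair %d: no admissible internal probe", p.rank)
        pairs = out
    stats["pairs_returned"] = len(pairs)
    return pairs, stats


def run_design(config: RunConfig) -> DesignBundle:
    """Execute the full workflow and return the in-memory bundle.

    Raises design.DesignError (with an explain report) when no candidate or
    no admissible pair exists; file problems raise their natural errors.
    """
    params = config.resolved_params()
    genome = reference.read_genome(config.fasta)
    transcript = None
    if params.is_cdna:
        if config.gff3 is None:
            raise ValueError("cDNA assays require --gff3")
        transcript = reference.load_transcript(config.gff3, genome, config.target)
        template = reference.extract_template(None, "cDNA", genome, transcript)
    else:
        template = reference.extract_template(
            config.target, "gDNA", genome, flank=config.flank
        )
    logger.info(
        "template: %s, %d bp, %d junctions",
        template.kind, len(template), len(template.junction_offsets),
    )
    pairs, stats = _design_pairs(template, params)

    spans: dict = {}
    for pair in pairs:
        for role in ("forward", "reverse", "probe"):
            cand = getattr(pair, role)
            if cand is None:
                continue
            spans[(pair.rank, role)] = coordinates.template_to_genome(
                cand.template_start, cand.length, template
            )

    tracks: dict = {}
    degenerates: dict = {}
    risk = None
    if config.vcf is not None:
        variants = variation.VariantTable.from_vcf(config.vcf)
        if config.metadata is not None:
            meta = pd.read_csv(config.metadata, sep="\t", dtype=str)
            cohort_ids = variation.select_cohort(meta, config.cohort)
        else:
            cohort_ids = list(variants.samples)
        stats["cohort_size"] = len(cohort_ids)
        for pair in pairs:
            for role, cand in [
                (r, c) for r in ("forward", "reverse", "probe")
                if (c := getattr(pair, r)) is not None
            ]:
                key = (pair.rank, role)
                track = variation.site_frequencies(
                    spans[key], variants, cohort_ids, cand.sequence,
                    orientation=cand.orientation,
                    oligo_name=f"pair{pair.rank}_{role}",
                )
                tracks[key] = track
                deg = variation.degenerate(
                    cand.sequence, track, config.risk_threshold
                )
                if deg.degeneracy > 1 or deg.flagged_indel_positions:
                    degenerates[key] = deg
        risk = variation.flag_risk(list(tracks.values()), config.risk_threshold)

    index = specificity.GenomeIndex(genome)
    intended = {
        pair.rank: (spans[(pair.rank, "forward")], spans[(pair.rank, "reverse")])
        for pair in pairs
    }
    verdicts = specificity.specificity_report(
        pairs, intended, index, config.max_mismatches
    )
    layout = coordinates.layout_report(pairs, template)
    return DesignBundle(
        config=config, template=template, pairs=pairs, spans=spans,
        tracks=tracks, risk=risk, degenerates=degenerates,
        verdicts=verdicts, layout=layout, stats=stats,
    )


def pairs_table(bundle: DesignBundle) -> pd.DataFrame:
    """Ranked pair table in the classic report schema: sequences, Tm, GC %,
    product size and genomic spans, one row per pair."""
    rows = []
    vd = {v.pair_rank: v for v in bundle.verdicts}
    for pair in bundle.pairs:
        row = {
            "pair": pair.rank,
            "forward_sequence": pair.forward.sequence,
            "reverse_sequence": pair.reverse.sequence,
            "forward_tm": round(pair.forward.thermo.tm_C, 2),
            "reverse_tm": round(pair.reverse.thermo.tm_C, 2),
            "forward_gc_pct": pair.forward.thermo.gc_pct,
            "reverse_gc_pct": pair.reverse.thermo.gc_pct,
            "product_size_bp": pair.product_size,
            "forward_genomic_span": bundle.spans[(pair.rank, "forward")].display,
            "reverse_genomic_span": bundle.spans[(pair.rank, "reverse")].display,
            "forward_spans_junction": pair.forward.spans_junction,
            "reverse_spans_junction": pair.reverse.spans_junction,
            "pair_penalty": round(pair.pair_penalty, 4),
            "specific": vd[pair.rank].specific,
        }
        if pair.probe is not None:
            row.update(
                probe_sequence=pair.probe.sequence,
                probe_tm=round(pair.probe.thermo.tm_C, 2),
                probe_gc_pct=pair.probe.thermo.gc_pct,
                probe_genomic_span=bundle.spans[(pair.rank, "probe")].display,
            )
        if bundle.tracks:
            for role in ("forward", "reverse"):
                t = bundle.tracks[(pair.rank, role)]
                row[f"{role}_max_alt_freq"] = round(t.max_freq, 4)
                row[f"{role}_n_segregating"] = sum(
                    s.segregating for s in t.sites
                )
        rows.append(row)
    return pd.DataFrame(rows)


def write_bundle(bundle: DesignBundle, outdir) -> dict[str, Path]:
    """Persist the bundle: primers.tsv, candidates.json, frequency tracks
    (TSV + plots), layout (JSON + plot), specificity verdicts and run
    statistics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tsv = outdir / "primers.tsv"
    pairs_table(bundle).to_csv(tsv, sep="\t", index=False)
    paths["primers"] = tsv

    cand_doc = []
    for pair in bundle.pairs:
        entry = {"rank": pair.rank, "product_size": pair.product_size,
                 "pair_penalty": pair.pair_penalty, "warnings": list(pair.warnings),
                 "oligos": {}}
        for role, cand in bundle.oligo_roles(pair):
            key = (pair.rank, role)
            o = {
                "sequence": cand.sequence,
                "template_start": cand.template_start,
                "length": cand.length,
                "orientation": cand.orientation,
                "penalty": cand.penalty,
                "spans_junction": cand.spans_junction,
                "thermo": dataclasses.asdict(cand.thermo),
                "genomic_span": {
                    "display": bundle.spans[key].display,
                    "blocks": [list(b) for b in bundle.spans[key].blocks],
                    "strand": bundle.spans[key].strand,
                },
            }
            if key in bundle.degenerates:
                o["degenerate"] = dataclasses.asdict(bundle.degenerates[key])
            entry["oligos"][role] = o
        cand_doc.append(entry)
    report = {
        "stats": bundle.stats,
        "pairs": cand_doc,
        "specificity": [dataclasses.asdict(v) for v in bundle.verdicts],
    }
    cj = outdir / "candidates.json"
    with open(cj, "w") as fh:
        json.dump(report, fh, indent=1)
    paths["candidates"] = cj

    if bundle.tracks:
        tdir = outdir / "tracks"
        tdir.mkdir(exist_ok=True)
        frames = []
        for (rank, role), track in sorted(bundle.tracks.items()):
            df = track.to_frame()
            df.insert(0, "oligo", track.oligo_name)
            frames.append(df)
            variation.plot_track(track, tdir / f"{track.oligo_name}.svg")
        pd.concat(frames).to_csv(tdir / "frequency_tracks.tsv", sep="\t", index=False)
        paths["tracks"] = tdir
    if bundle.risk is not None:
        rp = outdir / "risk.tsv"
        bundle.risk.to_csv(rp, sep="\t", index=False)
        paths["risk"] = rp

    lj = outdir / "layout.json"
    coordinates.write_layout_json(bundle.layout, lj)
    coordinates._plot_layout(bundle.layout, outdir / "layout.svg")
    paths["layout"] = lj

    cfg = outdir / "config.txt"
    with open(cfg, "w") as fh:
        doc = dataclasses.asdict(bundle.config)
        doc["params"] = dataclasses.asdict(bundle.config.resolved_params())
        for k, v in doc.items():
            fh.write(f"{k}: {v}\n")
    paths["config"] = cfg
    return paths
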