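"""Template <-> genome coordinate mapping and primer layout rendering.

A contiguous oligo occupies a single genomic block; an exon-junction
spanning oligo decomposes into 2+ blocks whose lengths sum to the oligo
length, and its display span ("contig:start-end", outermost coordinates)
is therefore longer than the oligo itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .reference import Template

__all__ = [
    "GenomicSpan",
    "template_to_genome",
    "genome_to_template",
    "oligo_base_positions",
    "layout_report",
]


@dataclass(frozen=True)
class GenomicSpan:
    """Genomic footprint of one oligo.

    blocks are (start, end) 1-based inclusive intervals on the forward
    genomic axis, sorted ascending; strand is the template strand the oligo
    was designed on ('+' for gDNA windows, transcript strand for cDNA).
    """

    contig: str
    strand: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("empty span")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if e1 >= s2:
                raise ValueError("blocks overlap or unsorted")
        if any(s > e for s, e in self.blocks):
            raise ValueError("malformed block")

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def display(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"

    @property
    def is_split(self) -> bool:
        return len(self.blocks) > 1


def _exon_cumlens(template: Template) -> list[tuple[int, int, tuple[int, int]]]:
    """(template_start, template_end, exon) per exon, template coords 0-based."""
    out = []
    cum = 0
    for exon in template.transcript.exons:
        ln = exon[1] - exon[0] + 1
        out.append((cum, cum + ln - 1, exon))
        cum += ln
    return out


def template_to_genome(start: int, length: int, template: Template) -> GenomicSpan:
    """Map a template-space interval (0-based start, length) to genomic
    blocks.  gDNA templates map by offset arithmetic; cDNA templates walk
    the exon chain, splitting at each junction the interval crosses.
    """
    if length < 1 or start < 0 or start + length > len(template):
        raise ValueError(
            f"interval [{start}, {start + length}) outside template "
            f"of length {len(template)}"
        )
    if template.transcript is None:
        g0 = template.window_start + start
        return GenomicSpan(
            contig=template.contig, strand="+", blocks=((g0, g0 + length - 1),)
        )
    tm = template.transcript
    t_lo, t_hi = start, start + length - 1
    blocks = []
    for ts, te, (gs, ge) in _exon_cumlens(template):
        lo, hi = max(ts, t_lo), min(te, t_hi)
        if lo > hi:
            continue
        if tm.strand == "+":
            blocks.append((gs + (lo - ts), gs + (hi - ts)))
        else:
            blocks.append((ge - (hi - ts), ge - (lo - ts)))
    blocks.sort()
    return GenomicSpan(contig=tm.contig, strand=tm.strand, blocks=tuple(blocks))


def genome_to_template(position: int, template: Template) -> int | None:
    """Inverse map: genomic position -> 0-based template position, or None
    for intronic / out-of-window positions."""
    if template.transcript is None:
        t = position - template.window_start
        return t if 0 <= t < len(template) else None
    for ts, _te, (gs, ge) in _exon_cumlens(template):
        if gs <= position <= ge:
            if template.transcript.strand == "+":
                return ts + (position - gs)
            return ts + (ge - position)
    return None


def oligo_base_positions(
    span: GenomicSpan, orientation: str = "forward"
) -> list[int]:
    """Genomic position of each oligo base in 5'->3' oligo order.

    Template order traverses blocks along the template strand; a reverse
    primer is the reverse complement of its template slice, so its 5'->3'
    order is the template order reversed.
    """
    blocks = list(span.blocks) if span.strand == "+" else list(span.blocks)[::-1]
    positions: list[int] = []
    for s, e in blocks:
        rng = range(s, e + 1) if span.strand == "+" else range(e, s - 1, -1)
        positions.extend(rng)
    if orientation == "reverse":
        positions.reverse()
    elif orientation != "forward":
        raise ValueError(f"bad orientation {orientation!r}")
    return positions


def layout_report(pairs, template: Template, plot_path=None) -> dict:
    """Primer-vs-exon layout: a JSON-ready dict with every block's
    coordinates and, optionally, a static plot (exon boxes, primer arrows;
    junction-spanning primers drawn expanded across the intron with
    sequence only at the extremities).
    """
    if not pairs:
        raise ValueError("layout_report: no pairs")
    tm = template.transcript
    layout: dict = {
        "contig": template.contig,
        "transcript": tm.transcript_id if tm else None,
        "strand": tm.strand if tm else "+",
        "exons": [list(e) for e in tm.exons] if tm else [],
        "primers": [],
    }
    for pair in pairs:
        for role in ("forward", "reverse", "probe"):
            cand = getattr(pair, role, None)
            if cand is None:
                continue
            span = template_to_genome(cand.template_start, cand.length, template)
            layout["primers"].append(
                {
                    "pair_rank": pair.rank,
                    "role": role,
                    "sequence": cand.sequence,
                    "orientation": cand.orientation,
                    "blocks": [list(b) for b in span.blocks],
                    "display": span.display,
                    "expanded": span.is_split,
                }
            )
    if plot_path is not None:
        _plot_layout(layout, plot_path)
    return layout


def _plot_layout(layout: dict, plot_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    for s, e in layout["exons"]:
        ax.fill_between([s, e], 0.8, 1.2, color="0.7", edgecolor="0.3")
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, p in enumerate(layout["primers"]):
        y = 1.5 + 0.25 * p["pair_rank"] + (0.1 if p["role"] == "reverse" else 0.0)
        col = colors[p["pair_rank"] % len(colors)]
        blocks = p["blocks"]
        if p["expanded"]:
            ax.plot(
                [blocks[0][1], blocks[-1][0]], [y, y], color=col, lw=0.8, ls=":"
            )
        for s, e in blocks:
            ax.plot([s, e], [y, y], color=col, lw=3, solid_capstyle="butt")
        tip = blocks[-1][1] if p["orientation"] == "forward" else blocks[0][0]
        ax.plot([tip], [y], marker=">" if p["orientation"] == "forward" else "<",
                color=col, ms=5)
    ax.set_yticks([])
    ax.set_xlabel(f"{layout['contig']} position (bp)")
    title = layout["transcript"] or layout["contig"]
    ax.set_title(f"primer layout: {title}")
    fig.tight_layout()
    fig.savefig(plot_path)
    plt.close(fig)


def write_layout_json(layout: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(layout, fh, indent=2)
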