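"""Primer and probe design engine.

Enumerates every window of allowed lengths on a template, applies hard
thermodynamic and structural filters, scores survivors with a weighted
deviation-from-optimum penalty, and assembles ranked primer pairs under
amplicon-size and (for cDNA assays) exon-junction-spanning constraints.

Deterministic throughout: ties are broken by (penalty, template position,
product size), so the same template and parameters always yield
byte-identical ranked output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import thermo
from .reference import Template
from .thermo import ReactionConditions, ThermoProfile, reverse_complement

__all__ = [
    "DesignParams",
    "PrimerCandidate",
    "PrimerPair",
    "DesignError",
    "enumerate_candidates",
    "penalty",
    "pair_candidates",
    "design_probe",
]

ASSAY_TYPES = ("gDNA_primers", "cDNA_primers", "gDNA_probe", "cDNA_probe")


class DesignError(RuntimeError):
    """Raised when no candidate or pair survives; carries the explain report
    so run statistics can be surfaced for troubleshooting."""

    def __init__(self, message: str, explain: dict):
        super().__init__(message)
        self.explain = explain


def _triple(lo, opt, hi, name):
    if not lo <= opt <= hi:
        raise ValueError(f"{name}: require min <= opt <= max, got {(lo, opt, hi)}")
    return (lo, opt, hi)


@dataclass(frozen=True)
class DesignParams:
    """All design tunables.  Bounds follow Primer3-style defaults; the
    amplicon range defaults to the short qPCR products (60-120 bp) typical
    of expression assays."""

    n_pairs: int = 5
    assay_type: str = "cDNA_primers"
    primer_len: tuple[int, int, int] = (18, 20, 25)
    tm: tuple[float, float, float] = (57.0, 60.0, 63.0)
    gc: tuple[float, float, float] = (30.0, 50.0, 70.0)
    amplicon_size: tuple[int, int] = (60, 120)
    # complementarity scores are complementary-pair *counts* (see thermo);
    # caps sit just above the bulk of random-oligo self-scores so only
    # unusually self-complementary oligos are killed
    max_any_complementarity: int = 12
    max_end_complementarity: int = 10
    max_hairpin: int = 24
    max_homopolymer: int = 4
    gc_clamp_cap: bool = True       # kill 3'-terminal runs of >=3 G/C
    junction_anchor: int = 4        # nt required on each side of a junction
    probe_len: tuple[int, int, int] = (18, 24, 30)
    probe_tm: tuple[float, float, float] = (64.0, 68.0, 72.0)
    probe_gc: tuple[float, float, float] = (30.0, 50.0, 80.0)
    probe_no_5prime_G: bool = True  # hydrolysis-probe convention
    conditions: ReactionConditions = ReactionConditions()
    # penalty weights
    w_tm: float = 1.0
    w_len: float = 1.0
    w_gc: float = 0.2
    w_self_any: float = 0.1
    w_self_end: float = 0.2
    w_end_stability: float = 0.1
    end_stability_cap: float = -9.0  # dG below this (more stable) is penalised
    w_tm_diff: float = 1.0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(f"assay_type must be one of {ASSAY_TYPES}")
        _triple(*self.primer_len, "primer_len")
        _triple(*self.tm, "tm")
        _triple(*self.gc, "gc")
        _triple(*self.probe_len, "probe_len")
        _triple(*self.probe_tm, "probe_tm")
        _triple(*self.probe_gc, "probe_gc")
        if not self.amplicon_size[0] < self.amplicon_size[1]:
            raise ValueError("amplicon_size: require min < max")

    @property
    def wants_probe(self) -> bool:
        return self.assay_type.endswith("_probe")

    @property
    def is_cdna(self) -> bool:
        return self.assay_type.startswith("cDNA")


# Primer3-style key aliases accepted in flat config files.
PRIMER3_ALIASES = {
    "PRIMER_NUM_RETURN": "n_pairs",
    "PRIMER_MIN_SIZE": ("primer_len", 0),
    "PRIMER_OPT_SIZE": ("primer_len", 1),
    "PRIMER_MAX_SIZE": ("primer_len", 2),
    "PRIMER_MIN_TM": ("tm", 0),
    "PRIMER_OPT_TM": ("tm", 1),
    "PRIMER_MAX_TM": ("tm", 2),
    "PRIMER_MIN_GC": ("gc", 0),
    "PRIMER_OPT_GC_PERCENT": ("gc", 1),
    "PRIMER_MAX_GC": ("gc", 2),
    "PRIMER_PRODUCT_SIZE_MIN": ("amplicon_size", 0),
    "PRIMER_PRODUCT_SIZE_MAX": ("amplicon_size", 1),
    "PRIMER_MAX_POLY_X": "max_homopolymer",
}


@dataclass(frozen=True)
class PrimerCandidate:
    """One oligo candidate.  ``sequence`` is 5'->3' as synthesised; reverse
    candidates are the reverse complement of their template slice."""

    sequence: str
    template_start: int
    length: int
    orientation: str
    thermo: ThermoProfile
    penalty: float
    spans_junction: bool = False
    role: str = "primer"

    @property
    def template_end(self) -> int:
        """0-based inclusive end on the template."""
        return self.template_start + self.length - 1

    @property
    def three_prime_template_pos(self) -> int:
        return self.template_end if self.orientation == "forward" else self.template_start


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    probe: PrimerCandidate | None
    product_size: int
    pair_penalty: float
    rank: int
    warnings: tuple[str, ...] = ()


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


_FILTER_ORDER = (
    "contains_N",
    "tm_bounds",
    "gc_bounds",
    "homopolymer",
    "gc_clamp",
    "self_any",
    "self_end",
    "hairpin",
)


def _passes_filters(
    seq: str,
    params: DesignParams,
    kills: dict[str, int],
    len_bounds,
    tm_bounds,
    gc_bounds,
) -> ThermoProfile | None:
    """Hard filters in fixed order; on failure increments the kill counter
    for the first failing filter and returns None."""
    if "N" in seq or set(seq) - set("ACGT"):
        kills["contains_N"] += 1
        return None
    tm = thermo.melting_temp(seq, params.conditions)
    if not tm_bounds[0] <= tm <= tm_bounds[2]:
        kills["tm_bounds"] += 1
        return None
    gc = thermo.gc_content(seq)
    if not gc_bounds[0] <= gc <= gc_bounds[2]:
        kills["gc_bounds"] += 1
        return None
    if _max_homopolymer(seq) > params.max_homopolymer:
        kills["homopolymer"] += 1
        return None
    if params.gc_clamp_cap and len(seq) >= 3 and all(c in "GC" for c in seq[-3:]):
        kills["gc_clamp"] += 1
        return None
    any_s, end_s = thermo.complementarity_scores(seq, seq)
    if any_s > params.max_any_complementarity:
        kills["self_any"] += 1
        return None
    if end_s > params.max_end_complementarity:
        kills["self_end"] += 1
        return None
    hp = thermo.hairpin_score(seq)
    if hp > params.max_hairpin:
        kills["hairpin"] += 1
        return None
    return ThermoProfile(
        tm_C=tm,
        gc_pct=gc,
        end_stability_dG=thermo.end_stability(seq),
        hairpin_score=hp,
        self_dimer_score=any_s,
        self_dimer_end_score=end_s,
    )


def _spans_junction(start: int, length: int, template: Template, anchor: int) -> bool:
    end = start + length - 1
    return any(
        (j - start) >= anchor and (end - j + 1) >= anchor
        for j in template.junction_offsets
    )


def penalty(profile: ThermoProfile, length: int, params: DesignParams,
            role: str = "primer") -> float:
    """Weighted deviation-from-optimum score; lower is better.

    penalty = w_tm*|Tm - Tm_opt| + w_len*|len - len_opt| + w_gc*|GC - GC_opt|
            + w_self_any*self_any + w_self_end*self_end
            + w_end_stability*max(0, end_stability_cap - dG_end)
    """
    if role == "probe":
        tm_opt, len_opt, gc_opt = params.probe_tm[1], params.probe_len[1], params.probe_gc[1]
    else:
        tm_opt, len_opt, gc_opt = params.tm[1], params.primer_len[1], params.gc[1]
    return (
        params.w_tm * abs(profile.tm_C - tm_opt)
        + params.w_len * abs(length - len_opt)
        + params.w_gc * abs(profile.gc_pct - gc_opt)
        + params.w_self_any * profile.self_dimer_score
        + params.w_self_end * profile.self_dimer_end_score
        + params.w_end_stability
        * max(0.0, params.end_stability_cap - profile.end_stability_dG)
    )


def enumerate_candidates(
    template: Template,
    params: DesignParams,
    orientation: str,
    role: str = "primer",
) -> list[PrimerCandidate]:
    """All windows of allowed lengths passing the hard filters, as scored
    candidates ordered by template position then length.

    Raises DesignError with a per-filter kill-count explain report when no
    window survives.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"bad orientation {orientation!r}")
    if role == "probe":
        len_bounds, tm_bounds, gc_bounds = params.probe_len, params.probe_tm, params.probe_gc
    else:
        len_bounds, tm_bounds, gc_bounds = params.primer_len, params.tm, params.gc
    n = len(template)
    if n < len_bounds[0]:
        raise DesignError(
            f"template ({n} bp) shorter than minimum {role} length",
            {"windows_considered": 0, "kills": {}},
        )
    kills = {k: 0 for k in _FILTER_ORDER}
    if role == "probe" and params.probe_no_5prime_G:
        kills["probe_5prime_G"] = 0
    out: list[PrimerCandidate] = []
    considered = 0
    for start in range(0, n - len_bounds[0] + 1):
        for length in range(len_bounds[0], len_bounds[2] + 1):
            if start + length > n:
                break
            considered += 1
            window = template.sequence[start : start + length]
            seq = window if orientation == "forward" else reverse_complement(window)
            if role == "probe" and params.probe_no_5prime_G and seq[0] == "G":
                kills["probe_5prime_G"] += 1
                continue
            profile = _passes_filters(seq, params, kills, len_bounds, tm_bounds, gc_bounds)
            if profile is None:
                continue
            out.append(
                PrimerCandidate(
                    sequence=seq,
                    template_start=start,
                    length=length,
                    orientation=orientation,
                    thermo=profile,
                    penalty=penalty(profile, length, params, role),
                    spans_junction=_spans_junction(
                        start, length, template, params.junction_anchor
                    ),
                    role=role,
                )
            )
    if not out:
        raise DesignError(
            f"no {orientation} {role} candidates survived the hard filters",
            {"windows_considered": considered, "kills": kills},
        )
    return out


def pair_candidates(
    fwd_list: list[PrimerCandidate],
    rev_list: list[PrimerCandidate],
    params: DesignParams,
    template: Template,
) -> list[PrimerPair]:
    """Rank all admissible forward/reverse combinations.

    Admissible: forward 3' end strictly left of reverse 3' end's 5' start on
    the template; product size (reverse 3'-most template base - forward
    5'-start + 1) within the amplicon range; for cDNA assays at least one
    mate spans an exon-exon junction unless the transcript is single-exon
    (warning attached).  Returns at most n_pairs pairs sorted by
    (pair_penalty, forward position, product size); no two returned pairs
    share both coordinates.
    """
    if not fwd_list or not rev_list:
        raise DesignError("empty candidate list", {"kills": {}})
    amp_lo, amp_hi = params.amplicon_size
    need_junction = params.is_cdna and bool(template.junction_offsets)
    single_exon_note = (
        params.is_cdna
        and not template.junction_offsets
        and template.kind == "cDNA"
    )
    kills = {"orientation": 0, "product_size": 0, "junction": 0}
    scored: list[tuple[float, int, int, PrimerCandidate, PrimerCandidate]] = []
    for f in fwd_list:
        for r in rev_list:
            if f.template_end >= r.template_start:
                kills["orientation"] += 1
                continue
            product = r.template_end - f.template_start + 1
            if not amp_lo <= product <= amp_hi:
                kills["product_size"] += 1
                continue
            if need_junction and not (f.spans_junction or r.spans_junction):
                kills["junction"] += 1
                continue
            pen = (
                f.penalty
                + r.penalty
                + params.w_tm_diff * abs(f.thermo.tm_C - r.thermo.tm_C)
            )
            scored.append((pen, f.template_start, product, f, r))
    if not scored:
        raise DesignError(
            "no admissible primer pair",
            {"kills": kills, "forward_candidates": len(fwd_list),
             "reverse_candidates": len(rev_list)},
        )
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    pairs: list[PrimerPair] = []
    seen: set[tuple[int, int, int, int]] = set()
    notes = ("single-exon transcript: junction spanning not available",) if single_exon_note else ()
    for pen, _fs, product, f, r in scored:
        key = (f.template_start, f.length, r.template_start, r.length)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(
            PrimerPair(
                forward=f, reverse=r, probe=None,
                product_size=product, pair_penalty=pen,
                rank=len(pairs), warnings=notes,
            )
        )
        if len(pairs) == params.n_pairs:
            break
    return pairs


def design_probe(
    template: Template, params: DesignParams, between: PrimerPair
) -> PrimerCandidate | None:
    """Best internal hybridisation probe for one amplicon: the
    lowest-penalty forward-orientation window strictly between the forward
    primer's 3' end and the reverse primer's 3' end, not overlapping either
    primer's 3'-terminal base.  Returns None (never raises) when nothing
    fits."""
    lo = between.forward.template_end + 1     # first template base after fwd 3'
    hi = between.reverse.template_start - 1   # last base before rev 3'
    if hi - lo + 1 < params.probe_len[0]:
        return None
    inner = replace(
        template,
        sequence=template.sequence[lo : hi + 1],
        junction_offsets=[j - lo for j in template.junction_offsets if lo < j <= hi],
    )
    try:
        cands = enumerate_candidates(inner, params, "forward", role="probe")
    except DesignError:
        return None
    best = min(cands, key=lambda c: (c.penalty, c.template_start, c.length))
    return replace(best, template_start=best.template_start + lo)
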