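"""Sequence-level physical chemistry for oligonucleotide screening.

Melting temperatures are computed with the unified nearest-neighbor model
(Allawi & SantaLucia 1997 stacking parameters with the SantaLucia 1998
initiation/terminal corrections), the entropic salt correction
0.368 * (N-1) * ln[Na+], and the von Ahsen conversion of divalent cations to
an effective monovalent concentration, Na_eff = Na + 120 * sqrt(Mg - dNTP)
(all mM).  These are the conventions of the standard PCR design stacks, so
oligos screened here carry the Tm a bench scientist expects to see.

All functions are pure; sequences are uppercase ACGT strings read 5'->3'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ReactionConditions",
    "ThermoProfile",
    "DEFAULT_CONDITIONS",
    "gc_content",
    "melting_temp",
    "end_stability",
    "complementarity_scores",
    "hairpin_score",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Unified NN parameters: dH in kcal/mol, dS in cal/(mol*K), per 5'->3' dinucleotide
# on the top strand of a Watson-Crick duplex.
_NN_DH_DS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

# Duplex initiation at each terminal base pair.
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)

_R = 1.987  # gas constant, cal/(mol*K)

MIN_TM_LENGTH = 8
MAX_TM_LENGTH = 36


@dataclass(frozen=True)
class ReactionConditions:
    """Ionic and oligo concentrations of the PCR buffer.

    monovalent_mM : total monovalent cation (Na+ + K+ + Tris/2), mM
    divalent_mM   : Mg2+, mM
    dntp_mM       : total dNTP, mM (chelates Mg2+; subtracted before the
                    divalent-to-monovalent conversion, floored at 0)
    oligo_nM      : total single-strand oligo concentration C_T, nM
    """

    monovalent_mM: float = 50.0
    divalent_mM: float = 1.5
    dntp_mM: float = 0.6
    oligo_nM: float = 50.0

    def __post_init__(self) -> None:
        for name in ("monovalent_mM", "divalent_mM", "dntp_mM", "oligo_nM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def effective_monovalent_mM(self) -> float:
        return self.monovalent_mM + 120.0 * math.sqrt(
            max(self.divalent_mM - self.dntp_mM, 0.0)
        )


DEFAULT_CONDITIONS = ReactionConditions()


@dataclass(frozen=True)
class ThermoProfile:
    """Thermodynamic summary of one oligo under fixed reaction conditions."""

    tm_C: float
    gc_pct: float
    end_stability_dG: float
    hairpin_score: int
    self_dimer_score: int
    self_dimer_end_score: int


def _check_seq(seq: str, op: str) -> None:
    if not seq:
        raise ValueError(f"{op}: empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{op}: non-ACGT characters {sorted(bad)} in sequence")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """Percent G+C, rounded to one decimal (``55.0`` reported as ``55``)."""
    _check_seq(seq, "gc_content")
    pct = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
    return round(pct, 1)


def _nn_sums(seq: str) -> tuple[float, float]:
    dh, ds = 0.0, 0.0
    for first, last in ((seq[0], seq[-1]),):
        for base in (first, last):
            inc = _INIT_GC if base in "GC" else _INIT_AT
            dh += inc[0]
            ds += inc[1]
    for i in range(len(seq) - 1):
        pdh, pds = _NN_DH_DS[seq[i : i + 2]]
        dh += pdh
        ds += pds
    return dh, ds


def melting_temp(seq: str, cond: ReactionConditions = DEFAULT_CONDITIONS) -> float:
    """Nearest-neighbor duplex melting temperature in degrees C.

    Tm = dH / (dS_salt + R * ln(C_T / 4)) - 273.15, with the salt-corrected
    entropy dS_salt = dS + 0.368 * (N - 1) * ln([Na+_eff] in M).
    """
    _check_seq(seq, "melting_temp")
    n = len(seq)
    if not MIN_TM_LENGTH <= n <= MAX_TM_LENGTH:
        raise ValueError(
            f"melting_temp: length {n} outside [{MIN_TM_LENGTH}, {MAX_TM_LENGTH}]"
        )
    dh, ds = _nn_sums(seq)
    na_eff_M = cond.effective_monovalent_mM * 1e-3
    ds += 0.368 * (n - 1) * math.log(na_eff_M)
    ct_M = cond.oligo_nM * 1e-9
    return (dh * 1000.0) / (ds + _R * math.log(ct_M / 4.0)) - 273.15


def end_stability(seq: str) -> float:
    """Free energy (dG37, kcal/mol) of the four NN stacks in the 3' pentamer.

    More negative means a more stable 3' end (stronger mispriming potential).
    """
    _check_seq(seq, "end_stability")
    if len(seq) < 5:
        raise ValueError("end_stability: sequence shorter than 5 nt")
    tail = seq[-5:]
    dg = 0.0
    for i in range(4):
        dh, ds = _NN_DH_DS[tail[i : i + 2]]
        dg += dh - 310.15 * ds / 1000.0
    return dg


def _is_comp(a: str, b: str) -> bool:
    return b == a.translate(_COMPLEMENT)


def complementarity_scores(a: str, b: str) -> tuple[int, int]:
    """Ungapped complementarity screen of two oligos.

    Slides ``a`` (5'->3') against ``reverse(b)`` — i.e. the two strands in
    antiparallel register — over every ungapped offset and counts
    Watson-Crick complementary positions.  Returns ``(any_score,
    end_score)``: the maximum over all offsets, and the maximum over offsets
    whose overlap includes the 3'-terminal base of ``a``.
    """
    if not a or not b:
        raise ValueError("complementarity_scores: empty sequence")
    rb = b[::-1]
    la, lb = len(a), len(b)
    any_score = 0
    end_score = 0
    for shift in range(-(lb - 1), la):
        lo = max(0, shift)
        hi = min(la, shift + lb)
        if lo >= hi:
            continue
        count = sum(1 for i in range(lo, hi) if _is_comp(a[i], rb[i - shift]))
        any_score = max(any_score, count)
        if hi == la:  # alignment window covers a's 3' terminus
            end_score = max(end_score, count)
    return any_score, end_score


def hairpin_score(seq: str, min_loop: int = 3) -> int:
    """Ungapped self-folding screen: maximum number of complementary pairs
    (i, j) with j - i - 1 >= min_loop along any antiparallel fold axis.

    This is a counting screen, not a free-energy minimisation.
    """
    _check_seq(seq, "hairpin_score")
    n = len(seq)
    best = 0
    # fold axis indexed by c = i + j; pairs (i, c - i)
    for c in range(min_loop + 1, 2 * n - min_loop - 2):
        count = 0
        i_hi = (c - min_loop - 1) // 2
        for i in range(0, i_hi + 1):
            j = c - i
            if j >= n:
                continue
            if _is_comp(seq[i], seq[j]):
                count += 1
        best = max(best, count)
    return best


def thermo_profile(
    seq: str, cond: ReactionConditions = DEFAULT_CONDITIONS
) -> ThermoProfile:
    """Full thermodynamic profile used by the design filters."""
    any_s, end_s = complementarity_scores(seq, seq)
    return ThermoProfile(
        tm_C=melting_temp(seq, cond),
        gc_pct=gc_content(seq),
        end_stability_dG=end_stability(seq),
        hairpin_score=hairpin_score(seq),
        self_dimer_score=any_s,
        self_dimer_end_score=end_s,
    )
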