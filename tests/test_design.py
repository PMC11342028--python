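"""Design engine: candidate enumeration vs a brute-force oracle, penalty
monotonicity, pair assembly arithmetic and probe placement."""

import dataclasses

import pytest

from varprimer import design, thermo
from varprimer.design import (
    DesignError,
    DesignParams,
    PrimerCandidate,
    design_probe,
    enumerate_candidates,
    pair_candidates,
)
from varprimer.reference import Template
from varprimer.synthetic import generate, random_manifest
from varprimer.thermo import ThermoProfile, reverse_complement


def make_template(seq, offsets=(), window_start=1001):
    if offsets:
        return Template(sequence=seq, kind="cDNA", contig="c",
                        junction_offsets=list(offsets))
    return Template(sequence=seq, kind="gDNA", contig="c",
                    window_start=window_start)


PERMISSIVE = DesignParams(
    tm=(0.0, 60.0, 110.0), gc=(0.0, 50.0, 100.0),
    max_any_complementarity=10_000, max_end_complementarity=10_000,
    max_hairpin=10_000, max_homopolymer=10_000, gc_clamp_cap=False,
)


def brute_force_candidates(template, params, orientation):
    """Independent re-statement of the hard-filter rules: every window of
    every allowed length, each filter checked from its definition."""

    def max_run(s):
        best = run = 1
        for x, y in zip(s, s[1:]):
            run = run + 1 if x == y else 1
            best = max(best, run)
        return best

    found = []
    n = len(template)
    lo, _, hi = params.primer_len
    for length in range(lo, hi + 1):
        for start in range(0, n - length + 1):
            window = template.sequence[start:start + length]
            seq = window if orientation == "forward" else reverse_complement(window)
            if set(seq) - set("ACGT"):
                continue
            tm = thermo.melting_temp(seq, params.conditions)
            if not params.tm[0] <= tm <= params.tm[2]:
                continue
            gc = thermo.gc_content(seq)
            if not params.gc[0] <= gc <= params.gc[2]:
                continue
            if max_run(seq) > params.max_homopolymer:
                continue
            if params.gc_clamp_cap and all(c in "GC" for c in seq[-3:]):
                continue
            a, e = thermo.complementarity_scores(seq, seq)
            if a > params.max_any_complementarity:
                continue
            if e > params.max_end_complementarity:
                continue
            if thermo.hairpin_score(seq) > params.max_hairpin:
                continue
            found.append((start, length, seq))
    return sorted(found)


class TestEnumerate:
    def test_counting_formula_when_every_window_passes(self):
        t = make_template("ACGTTGCA" * 20)  # 160 bp
        cands = enumerate_candidates(t, PERMISSIVE, "forward")
        lo, _, hi = PERMISSIVE.primer_len
        expected = sum(len(t) - L + 1 for L in range(lo, hi + 1))
        assert len(cands) == expected

    def test_poly_a_template_killed_by_tm_gc_bounds(self):
        t = make_template("A" * 120)
        with pytest.raises(DesignError) as exc:
            enumerate_candidates(t, DesignParams(), "forward")
        kills = exc.value.explain["kills"]
        assert sum(kills.values()) == exc.value.explain["windows_considered"]
        assert kills["tm_bounds"] + kills["gc_bounds"] == sum(kills.values())

    def test_candidate_overlapping_N_is_discarded(self):
        t = make_template("ACGTTGCAAC" * 10 + "N" + "ACGTTGCAAC" * 10)
        cands = enumerate_candidates(t, PERMISSIVE, "forward")
        for c in cands:
            assert "N" not in t.sequence[c.template_start:c.template_start + c.length]

    @pytest.mark.parametrize("orientation", ["forward", "reverse"])
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_bruteforce_on_small_templates(self, seed, orientation,
                                                   tmp_path):
        files = generate(random_manifest(seed), tmp_path)
        from varprimer import reference
        g = reference.read_genome(files.fasta)
        t = make_template(g.contigs["chr1"][1000:1280])  # 280 bp slice
        params = DesignParams()
        oracle = brute_force_candidates(t, params, orientation)
        try:
            engine = sorted(
                (c.template_start, c.length, c.sequence)
                for c in enumerate_candidates(t, params, orientation)
            )
        except DesignError:
            engine = []
        assert engine == oracle

    def test_reverse_candidates_are_revcomp_of_template_slice(self):
        t = make_template("ACGTTGCAAC" * 12)
        for c in enumerate_candidates(t, PERMISSIVE, "reverse")[:50]:
            assert c.sequence == reverse_complement(
                t.sequence[c.template_start:c.template_start + c.length]
            )


class TestPenalty:
    def _profile(self, tm, gc, end_dg=-8.0, any_s=0, end_s=0):
        return ThermoProfile(tm_C=tm, gc_pct=gc, end_stability_dG=end_dg,
                             hairpin_score=0, self_dimer_score=any_s,
                             self_dimer_end_score=end_s)

    def test_zero_deviation_at_optima(self):
        p = DesignParams()
        prof = self._profile(p.tm[1], p.gc[1])
        assert design.penalty(prof, p.primer_len[1], p) == 0.0

    def test_larger_tm_deviation_larger_penalty(self):
        p = DesignParams()
        a = design.penalty(self._profile(p.tm[1] + 1, p.gc[1]), p.primer_len[1], p)
        b = design.penalty(self._profile(p.tm[1] + 3, p.gc[1]), p.primer_len[1], p)
        assert b > a > 0

    def test_documented_formula_oracle(self):
        p = DesignParams()
        prof = self._profile(61.5, 45.0, end_dg=-10.2, any_s=4, end_s=2)
        expected = (
            p.w_tm * abs(61.5 - p.tm[1])
            + p.w_len * abs(22 - p.primer_len[1])
            + p.w_gc * abs(45.0 - p.gc[1])
            + p.w_self_any * 4 + p.w_self_end * 2
            + p.w_end_stability * max(0.0, p.end_stability_cap - (-10.2))
        )
        assert design.penalty(prof, 22, p) == pytest.approx(expected)


def _candidate(seq, start, orientation="forward", spans_junction=False,
               penalty=1.0):
    prof = ThermoProfile(tm_C=60.0, gc_pct=50.0, end_stability_dG=-8.0,
                         hairpin_score=0, self_dimer_score=0,
                         self_dimer_end_score=0)
    return PrimerCandidate(sequence=seq, template_start=start, length=len(seq),
                           orientation=orientation, thermo=prof,
                           penalty=penalty, spans_junction=spans_junction)


class TestPairing:
    def test_product_size_arithmetic(self):
        """Forward at 0-19, reverse ending at template 72 -> 73 bp product."""
        t = make_template("ACGTTGCAAC" * 10)
        f = _candidate("A" * 20, 0)
        r = _candidate("A" * 20, 53, "reverse")  # occupies 53..72
        pairs = pair_candidates([f], [r], DesignParams(assay_type="gDNA_primers"), t)
        assert len(pairs) == 1
        assert pairs[0].product_size == 73

    def test_all_products_outside_range_explains(self):
        t = make_template("ACGTTGCAAC" * 30)
        f = _candidate("A" * 20, 0)
        r = _candidate("A" * 20, 260, "reverse")  # product 280 > 120
        with pytest.raises(DesignError) as exc:
            pair_candidates([f], [r], DesignParams(assay_type="gDNA_primers"), t)
        assert exc.value.explain["kills"]["product_size"] == 1

    def test_cdna_requires_junction_spanning_mate(self):
        t = make_template("ACGTTGCAAC" * 10, offsets=[50])
        params = DesignParams(amplicon_size=(40, 120))
        f_nj = _candidate("A" * 20, 0, penalty=0.1)
        r_nj = _candidate("A" * 20, 75, "reverse", penalty=0.1)
        with pytest.raises(DesignError) as exc:
            pair_candidates([f_nj], [r_nj], params, t)
        assert exc.value.explain["kills"]["junction"] == 1
        f_j = _candidate("C" * 20, 40, spans_junction=True, penalty=5.0)
        pairs = pair_candidates([f_nj, f_j], [r_nj], params, t)
        assert all(p.forward.spans_junction or p.reverse.spans_junction
                   for p in pairs)

    def test_single_exon_transcript_pairs_carry_warning(self, genome, fixture_dir):
        from varprimer import reference
        tm = reference.load_transcript(fixture_dir.gff3, genome, "G3-RA")
        t = reference.extract_template(None, "cDNA", genome, tm)
        params = DesignParams()
        fwd = enumerate_candidates(t, params, "forward")
        rev = enumerate_candidates(t, params, "reverse")
        pairs = pair_candidates(fwd, rev, params, t)
        assert pairs
        assert any("single-exon" in w for w in pairs[0].warnings)

    def test_ranked_output_sorted_and_bounded(self, template_g1):
        params = DesignParams(n_pairs=5)
        fwd = enumerate_candidates(template_g1, params, "forward")
        rev = enumerate_candidates(template_g1, params, "reverse")
        pairs = pair_candidates(fwd, rev, params, template_g1)
        assert len(pairs) <= params.n_pairs
        pens = [p.pair_penalty for p in pairs]
        assert pens == sorted(pens)
        lo, hi = params.amplicon_size
        assert all(lo <= p.product_size <= hi for p in pairs)
        coords = {(p.forward.template_start, p.forward.length,
                   p.reverse.template_start, p.reverse.length) for p in pairs}
        assert len(coords) == len(pairs)

    def test_determinism_byte_identical_ranking(self, template_g1):
        params = DesignParams(n_pairs=5)

        def run():
            f = enumerate_candidates(template_g1, params, "forward")
            r = enumerate_candidates(template_g1, params, "reverse")
            return [(p.forward.sequence, p.reverse.sequence, p.product_size,
                     p.pair_penalty) for p in pair_candidates(f, r, params, template_g1)]

        assert run() == run()


class TestProbe:
    def test_amplicon_too_short_returns_none(self):
        t = make_template("ACGTTGCAAC" * 10)
        f = _candidate("A" * 20, 0)
        r = _candidate("A" * 20, 45, "reverse")  # 25 nt gap > needs 18? gap=25
        params = DesignParams(assay_type="gDNA_probe",
                              probe_len=(30, 30, 30))
        pair = design.PrimerPair(forward=f, reverse=r, probe=None,
                                 product_size=65, pair_penalty=0, rank=0)
        assert design_probe(t, params, pair) is None

    def test_probe_contained_between_primers(self, template_g1):
        params = DesignParams(assay_type="cDNA_probe", n_pairs=3,
                              amplicon_size=(80, 120))
        fwd = enumerate_candidates(template_g1, params, "forward")
        rev = enumerate_candidates(template_g1, params, "reverse")
        pairs = pair_candidates(fwd, rev, params, template_g1)
        probes = [(p, design_probe(template_g1, params, p)) for p in pairs]
        found = [(p, pr) for p, pr in probes if pr is not None]
        assert found, "no pair admitted an internal probe"
        for pair, probe in found:
            assert probe.template_start > pair.forward.template_end
            assert (probe.template_start + probe.length - 1
                    < pair.reverse.template_start)
            assert not probe.sequence.startswith("G")

    def test_probe_is_best_admissible_window(self):
        t = make_template("ACGTTGCAACGGATCCATTGCAAGCTTACGTTGCAACGGATCCATTGCA"
                          "AGCTTACGTTGCAACGGATCC")
        f = _candidate("A" * 18, 0)
        r = _candidate("A" * 18, len(t) - 18, "reverse")
        params = dataclasses.replace(
            PERMISSIVE, assay_type="gDNA_probe", probe_tm=(0.0, 68.0, 110.0),
            probe_gc=(0.0, 50.0, 100.0),
        )
        pair = design.PrimerPair(forward=f, reverse=r, probe=None,
                                 product_size=len(t), pair_penalty=0, rank=0)
        probe = design_probe(t, params, pair)
        assert probe is not None
        lo = f.template_end + 1
        hi = r.template_start - 1
        best = None
        for L in range(params.probe_len[0], params.probe_len[2] + 1):
            for s in range(lo, hi - L + 2):
                seq = t.sequence[s:s + L]
                if params.probe_no_5prime_G and seq.startswith("G"):
                    continue
                prof = design._passes_filters(
                    seq, params, {k: 0 for k in design._FILTER_ORDER},
                    params.probe_len, params.probe_tm, params.probe_gc)
                if prof is None:
                    continue
                pen = design.penalty(prof, L, params, role="probe")
                key = (pen, s, L)
                if best is None or key < best[0]:
                    best = (key, seq)
        assert best is not None
        assert (probe.penalty, probe.template_start, probe.length) == best[0]
        assert probe.sequence == best[1]
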