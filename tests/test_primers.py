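"""Degenerate-primer evaluation: expansion, matching, in-silico PCR, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cablecensus.primers import (
    DegeneratePrimer,
    count_mismatches,
    expand_degenerate,
    find_binding_sites,
    in_silico_pcr,
    load_qpcr_primers,
    primer_qc,
    revcomp,
    specificity_screen,
)


def _background(length, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


class TestExpansion:
    def test_family_forward_primer_has_two_variants(self, qpcr_primers):
        variants = expand_degenerate(qpcr_primers["DSBB280wF"])
        assert variants == {"CGATGGTTAACGGGTCTG", "CGATGGTTAGCGGGTCTG"}
        # the two variants differ exactly at position 10
        a, b = sorted(variants)
        diffs = [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]
        assert diffs == [10]

    def test_non_degenerate_primer_expands_to_itself(self, qpcr_primers):
        p = qpcr_primers["ELF645F"]
        assert expand_degenerate(p) == {p.sequence}
        assert p.degeneracy == 1

    def test_n_gives_four_variants(self):
        p = DegeneratePrimer("x", "ACGTACGTACNT")
        assert p.degeneracy == 4
        assert len(expand_degenerate(p)) == 4

    def test_count_matches_degeneracy_product(self, qpcr_primers):
        for p in qpcr_primers.values():
            assert len(expand_degenerate(p)) == p.degeneracy

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            DegeneratePrimer("bad", "ACGTACGTXA")


class TestCountMismatches:
    def test_marina_variant_site_vs_original_primer(self, qpcr_primers):
        # the wobble primer's C-at-2 expansion has one mismatch to the
        # original narrow primer, at position 2
        site = "CCTGGCTTGAGTATCAGAGG"
        assert site in expand_degenerate(qpcr_primers["ELF645wF"])
        n, pos = count_mismatches(qpcr_primers["ELF645F"], site)
        assert (n, pos) == (1, (2,))

    def test_family_primer_variant_at_position_10(self, qpcr_primers):
        site = "CGATGGTTAACGGGTCTG"
        n, pos = count_mismatches(qpcr_primers["DSBB280F"], site)
        assert (n, pos) == (1, (10,))

    def test_degenerate_self_match(self, qpcr_primers):
        for site in expand_degenerate(qpcr_primers["ELF645wF"]):
            assert count_mismatches(qpcr_primers["ELF645wF"], site) == (0, ())

    def test_template_n_counts_as_mismatch(self):
        p = DegeneratePrimer("x", "ACGTACGTAC")
        n, pos = count_mismatches(p, "ACGTNCGTAC")
        assert (n, pos) == (1, (5,))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            count_mismatches(DegeneratePrimer("x", "ACGTACGTAC"), "ACGT")


class TestBindingSites:
    def test_planted_exact_site_found(self, qpcr_primers):
        p = qpcr_primers["ELF645wF"]
        site = sorted(expand_degenerate(p))[0]
        template = _background(200, 1)[:80] + site + _background(200, 2)[:100]
        hits = find_binding_sites(p, template, 0)
        assert len(hits) == 1
        assert hits[0].start == 80
        assert hits[0].mismatches == 0

    def test_planted_mismatches_respect_allowance(self, qpcr_primers):
        p = qpcr_primers["ELF645wF"]
        site = list(sorted(expand_degenerate(p))[0])
        # substitutions at primer positions 2, 3, 5 (bases outside the code set)
        for pos in (2, 3, 5):
            site[pos - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[pos - 1]]
        template = _background(60, 3) + "".join(site) + _background(60, 4)
        assert find_binding_sites(p, template, 2) == []
        hits = find_binding_sites(p, template, 3)
        assert len(hits) == 1
        assert hits[0].mismatch_positions == (2, 3, 5)

    def test_reverse_primer_binds_revcomp_site(self, qpcr_primers):
        rev = qpcr_primers["CB836wR"]
        site = revcomp(sorted(expand_degenerate(rev))[0])
        template = _background(50, 5) + site + _background(50, 6)
        hits = find_binding_sites(rev, template, 0)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].start == 50

    def test_three_prime_exact_zone(self):
        p = DegeneratePrimer("x", "ACGTACGTACGT")
        site = "ACGTACGTACGA"  # mismatch at position 12 (3' terminal)
        template = _background(30, 7) + site + _background(30, 8)
        assert find_binding_sites(p, template, 1)
        assert find_binding_sites(p, template, 1, three_prime_exact=2) == []

    @given(st.data())
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_zero_mismatch_search_equals_expanded_substring_search(self, data):
        pseq = data.draw(
            st.text(alphabet="ACGTRYN", min_size=10, max_size=12).filter(
                lambda s: sum(c in "RYN" for c in s) <= 3
            )
        )
        template = data.draw(st.text(alphabet="ACGT", min_size=40, max_size=80))
        primer = DegeneratePrimer("p", pseq)
        # plant one expansion so hits actually occur
        planted = sorted(expand_degenerate(primer))[0]
        template = template + planted + template[:10]
        found = {s.start for s in find_binding_sites(primer, template, 0)}
        oracle = {
            i
            for v in expand_degenerate(primer)
            for i in range(len(template) - len(v) + 1)
            if template[i : i + len(v)] == v
        }
        assert found == oracle

    @given(st.integers(0, 3))
    @settings(deadline=None, max_examples=4)
    def test_hits_monotone_in_mismatch_allowance(self, qpcr_primers, m):
        p = qpcr_primers["ELF645wF"]
        template = _background(400, 9)
        a = len(find_binding_sites(p, template, m))
        b = len(find_binding_sites(p, template, m + 1))
        assert b >= a

    def test_revcomp_symmetry(self, qpcr_primers):
        # a forward primer on t finds the same sites as the same sequence
        # probed as a reverse primer on revcomp(t), with mirrored coordinates
        p = qpcr_primers["ELF645wF"]
        site = sorted(expand_degenerate(p))[0]
        t = _background(60, 10) + site + _background(40, 11)
        as_rev = DegeneratePrimer(p.name, p.sequence, "reverse")
        fwd_hits = find_binding_sites(p, t, 1)
        rev_hits = find_binding_sites(as_rev, revcomp(t), 1)
        assert {(h.start, h.mismatches) for h in fwd_hits} == {
            (len(t) - h.end, h.mismatches) for h in rev_hits
        }


class TestInSilicoPCR:
    def _template_with_product(self, fwd, rev, amp_len, fwd_at=100, total=500):
        t = list(_background(total, 12))
        fsite = sorted(expand_degenerate(fwd))[0]
        rsite = revcomp(sorted(expand_degenerate(rev))[0])
        t[fwd_at : fwd_at + len(fwd)] = fsite
        t[fwd_at + amp_len - len(rev) : fwd_at + amp_len] = rsite
        return "".join(t)

    def test_planted_191_bp_product(self, qpcr_primers):
        fwd, rev = qpcr_primers["ELF645wF"], qpcr_primers["CB836wR"]
        t = self._template_with_product(fwd, rev, 191)
        amps = in_silico_pcr(fwd, rev, t, 0, 200)
        assert len(amps) == 1
        assert amps[0].length == 191
        assert amps[0].start == 100

    def test_reverse_site_upstream_gives_no_product(self, qpcr_primers):
        fwd, rev = qpcr_primers["ELF645wF"], qpcr_primers["CB836wR"]
        t = list(_background(400, 13))
        rsite = revcomp(sorted(expand_degenerate(rev))[0])
        fsite = sorted(expand_degenerate(fwd))[0]
        t[50 : 50 + len(rev)] = rsite
        t[200 : 200 + len(fwd)] = fsite
        assert in_silico_pcr(fwd, rev, "".join(t), 0, 400) == []

    def test_two_forward_sites_two_products(self, qpcr_primers):
        fwd, rev = qpcr_primers["ELF645wF"], qpcr_primers["CB836wR"]
        t = list(_background(500, 14))
        fsite = sorted(expand_degenerate(fwd))[0]
        rsite = revcomp(sorted(expand_degenerate(rev))[0])
        t[50 : 50 + len(fwd)] = fsite
        t[120 : 120 + len(fwd)] = fsite
        t[230 : 230 + len(rev)] = rsite
        amps = in_silico_pcr(fwd, rev, "".join(t), 0, 400)
        assert len(amps) == 2
        assert {a.start for a in amps} == {50, 120}

    def test_amplicon_length_cap(self, qpcr_primers):
        fwd, rev = qpcr_primers["ELF645wF"], qpcr_primers["CB836wR"]
        t = self._template_with_product(fwd, rev, 250)
        assert in_silico_pcr(fwd, rev, t, 0, 200) == []
        assert len(in_silico_pcr(fwd, rev, t, 0, 300)) == 1


class TestPrimerQC:
    def test_universal_reverse_primer_gc_out_of_band(self, qpcr_primers):
        rep = primer_qc(qpcr_primers["Eub518"])
        assert rep.gc_percent_range[0] == pytest.approx(64.7, abs=0.05)
        assert not rep.gc_in_band

    def test_exact_revcomp_partner_flags_hetero_dimer(self):
        p = DegeneratePrimer("p", "ACTGGCAAGTCCATGA")
        q = DegeneratePrimer("q", revcomp(p.sequence))
        rep = primer_qc(p, partner=q)
        assert rep.hetero_dimer

    def test_degenerate_primer_reports_gc_range(self, qpcr_primers):
        rep = primer_qc(qpcr_primers["DSBB280wF"])
        lo, hi = rep.gc_percent_range
        # the A/G wobble shifts GC by exactly one base in 18
        assert hi - lo == pytest.approx(100 / 18, abs=0.01)

    def test_hairpin_detection(self):
        stem = "GGGGCATT"
        hairpin_seq = stem + "AAA" + revcomp(stem)
        rep = primer_qc(DegeneratePrimer("hp", hairpin_seq))
        assert rep.hairpin
        rep2 = primer_qc(DegeneratePrimer("ok", "ACACACACACAC"))
        assert not rep2.hairpin

    def test_tm_range_and_clamp_reported(self, qpcr_primers):
        rep = primer_qc(qpcr_primers["ELF645wF"])
        assert rep.tm_range_c[0] <= rep.tm_range_c[1]
        assert 40 < rep.tm_range_c[0] < 80
        assert 0 <= rep.three_prime_gc_count <= 5


class TestSpecificityScreen:
    def test_empty_reference_set(self, qpcr_primers):
        rep = specificity_screen(
            (qpcr_primers["ELF645wF"], qpcr_primers["CB836wR"]), {}, {}
        )
        assert rep.counts.empty

    def test_missing_taxonomy_excluded_with_warning(self, qpcr_primers):
        p = qpcr_primers["ELF645wF"]
        refs = {"a": _background(100, 15), "b": _background(100, 16)}
        rep = specificity_screen(p, refs, {"a": "Bacteria;X"})
        assert rep.skipped == ("b",)
        assert set(rep.counts["taxon"]) == {"Bacteria;X"}

    def test_pair_hits_bounded_by_single_hits(self, qpcr_primers):
        from cablecensus.synthetic import gen_reference_db

        fwd, rev = qpcr_primers["ELF645wF"], qpcr_primers["CB836wR"]
        refs, tax, _ = gen_reference_db(6, 4, fwd, rev, {"rev": [5]}, seed=21)
        pair = specificity_screen((fwd, rev), refs, tax, (0, 1))
        single_f = specificity_screen(fwd, refs, tax, (0, 1))
        single_r = specificity_screen(rev, refs, tax, (0, 1))
        for taxon in pair.counts["taxon"].unique():
            for level in (0, 1):
                assert pair.hits(taxon, level) <= min(
                    single_f.hits(taxon, level), single_r.hits(taxon, level)
                )
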