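"""PAM scanning, cross-species window mapping, specificity scoring, verdicts.

Brute-force re-implementations (naive per-position window tests, naive
per-column alignment walks) serve as independent oracles.
"""

import itertools

import pytest

from pestid.guides import (
    GuideCandidate,
    PamSpec,
    SeedSpec,
    SpecificityReport,
    classify_guide,
    design_guides,
    enumerate_guides,
    map_window_across_species,
    rank_candidates,
    scan_pam_sites,
    score_specificity,
    verify_guides,
)
from pestid.regions import (
    build_concatenated_template,
    conservation_profile,
    find_conserved_blocks,
    find_variable_regions,
)
from pestid.seqio import msa_from_strings
from pestid.synthetic import PanelSpec, generate_panel

from conftest import random_seq

# independent IUPAC table for the oracles
IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
         "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
         "V": "ACG", "N": "ACGT"}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_rc(seq):
    return "".join(COMP[c] for c in reversed(seq))


def brute_pam_scan(seq, pattern="TTTV", plen_spacer=20, excluded=()):
    wlen = len(pattern) + plen_spacer
    hits = []
    for pos in range(len(seq) - wlen + 1):
        if any(pos < e and s < pos + wlen for s, e in excluded):
            continue
        window = seq[pos:pos + wlen]
        if any(c not in "ACGT" for c in window):
            continue
        if all(window[i] in IUPAC[pattern[i]] for i in range(len(pattern))):
            hits.append((pos, "+"))
        rc = brute_rc(window)
        if all(rc[i] in IUPAC[pattern[i]] for i in range(len(pattern))):
            hits.append((pos, "-"))
    return hits


class TestScanPamSites:
    def test_single_forward_site(self):
        seq = "TTTA" + "C" * 21
        assert scan_pam_sites(seq, PamSpec())[:1] == [(0, "+")]
        assert scan_pam_sites(seq, PamSpec()) == [(0, "+")]

    def test_reverse_strand_site(self):
        # bottom strand reads TTTA + G*20; top strand is its reverse complement
        seq = brute_rc("TTTA" + "G" * 20)
        assert scan_pam_sites(seq, PamSpec()) == [(0, "-")]

    def test_site_inside_excluded_interval_dropped(self):
        seq = "TTTA" + "C" * 21
        assert scan_pam_sites(seq, PamSpec(), excluded=[(2, 6)]) == []
        # an exclusion clear of the window leaves the site alone
        assert (0, "+") in scan_pam_sites(seq, PamSpec(), excluded=[(26, 40)])

    def test_ambiguous_window_dropped(self):
        seq = "TTTA" + "C" * 10 + "N" + "C" * 10
        assert scan_pam_sites(seq, PamSpec()) == []

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(40):
            seq = random_seq(rng, 1000, alphabet="ACGTN")
            excluded = []
            if rng.random() < 0.5:
                s = int(rng.integers(0, 900))
                excluded = [(s, s + int(rng.integers(5, 60)))]
            assert scan_pam_sites(seq, PamSpec(), excluded) == brute_pam_scan(
                seq, excluded=excluded
            )

    def test_reverse_complement_mirror_symmetry(self, rng):
        """Scanning the reverse complement yields the mirrored hit set."""
        for _ in range(20):
            seq = random_seq(rng, 300)
            wlen = PamSpec().window_len
            hits = scan_pam_sites(seq, PamSpec())
            mirrored = sorted(
                (len(seq) - (pos + wlen), "-" if strand == "+" else "+")
                for pos, strand in hits
            )
            assert sorted(scan_pam_sites(brute_rc(seq), PamSpec())) == mirrored

    def test_gapped_sequence_rejected(self):
        with pytest.raises(ValueError):
            scan_pam_sites("TTT-A" + "C" * 30, PamSpec())


class TestMapWindowAcrossSpecies:
    def test_identical_alignment_round_trips(self):
        msa = msa_from_strings([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        window, indel = map_window_across_species(msa, "a", (2, 6), "b")
        assert window == "GTAC"
        assert indel is False

    def test_gap_in_target_sets_indel_flag(self):
        msa = msa_from_strings([("a", "ACGTACGT"), ("b", "AC-TACGT")])
        window, indel = map_window_across_species(msa, "a", (1, 4), "b")
        assert window == "C-T"
        assert indel is True

    def test_insertion_in_target_sets_indel_flag(self):
        msa = msa_from_strings([("a", "AC--GT"), ("b", "ACTTGT")])
        window, indel = map_window_across_species(msa, "a", (1, 3), "b")
        assert window == "CTTG"
        assert indel is True

    def test_agrees_with_naive_column_walk(self, rng):
        from conftest import random_gapped_msa

        for _ in range(100):
            msa = random_gapped_msa(rng, 3, int(rng.integers(10, 60)))
            origin, target = "sp1", "sp2"
            aligned_o = msa.record(origin).residues
            aligned_t = msa.record(target).residues
            positions = [c for c, ch in enumerate(aligned_o) if ch != "-"]
            if len(positions) < 3:
                continue
            lo = int(rng.integers(0, len(positions) - 2))
            hi = int(rng.integers(lo + 1, len(positions)))
            c0, c1 = positions[lo], positions[hi - 1] + 1
            expect = aligned_t[c0:c1]
            expect_indel = any(
                (aligned_o[c] == "-") != (aligned_t[c] == "-") for c in range(c0, c1)
            )
            assert map_window_across_species(msa, origin, (lo, hi), target) == (
                expect, expect_indel
            )

    def test_out_of_range_interval_raises(self):
        msa = msa_from_strings([("a", "ACGT"), ("b", "ACGT")])
        with pytest.raises(IndexError):
            map_window_across_species(msa, "a", (2, 9), "b")


def _candidate_on(msa, species, start, strand="+"):
    """Build a 24-nt window candidate anchored at an ungapped start position."""
    full = msa.ungapped(species)
    window = full[start:start + 24]
    oriented = window if strand == "+" else brute_rc(window)
    return GuideCandidate(
        guide_id="t", origin_species=species, region_label="VR1", strand=strand,
        pam_seq=oriented[:4], protospacer=oriented[4:],
        origin_interval=(start, start + 24), gc_fraction=0.5,
    )


class TestScoreSpecificity:
    def _flanked(self, core_by_species):
        """Embed per-species 24-nt cores between shared flanks."""
        left, right = "ACGAT" * 4, "TCAGG" * 4
        return msa_from_strings(
            [(sp, left + core + right) for sp, core in core_by_species.items()]
        )

    def test_identical_off_species_is_cross_reactive(self):
        core = "TTTA" + "ACGTC" * 4
        msa = self._flanked({"a": core, "b": core})
        (report,) = score_specificity(_candidate_on(msa, "a", 20), msa)
        assert report.pam_intact and report.total_mismatches == 0
        assert report.cross_reactive

    def test_single_thymine_pam_loss_blocks_recognition(self):
        core = "TTTA" + "ACGTC" * 4
        msa = self._flanked({"a": core, "b": "TCTA" + "ACGTC" * 4})
        (report,) = score_specificity(_candidate_on(msa, "a", 20), msa)
        assert not report.pam_intact
        assert report.total_mismatches == 0
        assert not report.cross_reactive

    def test_two_mismatches_one_in_seed_blocks_recognition(self):
        proto_a = "ACGTCACGTCACGTCACGTC"
        proto_b = "ACGACACGTCACGGCACGTC"  # mismatches at indices 3 (seed) and 13
        msa = self._flanked({"a": "TTTA" + proto_a, "b": "TTTA" + proto_b})
        (report,) = score_specificity(_candidate_on(msa, "a", 20), msa)
        assert report.pam_intact
        assert report.total_mismatches == 2
        assert report.seed_mismatches == 1
        assert not report.cross_reactive

    def test_seed_counted_from_pam_on_reverse_strand(self):
        # '-' strand window: PAM at the right end in forward coordinates,
        # seed = the 10 forward-coordinate bases immediately left of the PAM
        core_a = brute_rc("TTTA" + "ACGTCACGTCACGTCACGTC")
        core_b = list(core_a)
        core_b[12] = {"A": "C"}.get(core_b[12], "A")  # inside forward seed [10,20)
        core_b[2] = {"A": "C"}.get(core_b[2], "A")    # outside the seed
        msa = self._flanked({"a": core_a, "b": "".join(core_b)})
        (report,) = score_specificity(_candidate_on(msa, "a", 20, strand="-"), msa)
        assert report.total_mismatches == 2
        assert report.seed_mismatches == 1

    def test_mismatch_counts_match_brute_force_on_panels(self, rng):
        checked = 0
        for seed in range(6):
            truth = generate_panel(PanelSpec(n_species=3, rng_seed=900 + seed))
            msa = truth.msa
            profile = conservation_profile(msa)
            regions = find_variable_regions(profile, find_conserved_blocks(profile), msa)
            template = build_concatenated_template(regions, msa)
            for cand in enumerate_guides(template):
                reports = score_specificity(cand, msa)
                for report in reports:
                    expect = brute_specificity(msa, cand, report.species)
                    assert (report.total_mismatches, report.seed_mismatches,
                            report.pam_intact, report.indel_in_window) == expect
                    checked += 1
        assert checked >= 100

    def test_empty_reports_refused_by_classifier(self):
        with pytest.raises(ValueError):
            classify_guide([])


def brute_specificity(msa, cand, target):
    """Naive alignment walk: recompute (mm, seed_mm, pam_intact, indel)."""
    aligned_o = msa.record(cand.origin_species).residues
    aligned_t = msa.record(target).residues
    pos_cols = [c for c, ch in enumerate(aligned_o) if ch != "-"]
    start, end = cand.origin_interval
    cols = pos_cols[start:end]
    span = range(cols[0], cols[-1] + 1)
    indel = any((aligned_o[c] == "-") != (aligned_t[c] == "-") for c in span)
    if cand.strand == "+":
        pam_cols, proto_cols = cols[:4], cols[4:]
        seed_cols = proto_cols[:10]
        pam_str = "".join(aligned_t[c] for c in pam_cols)
    else:
        pam_cols, proto_cols = cols[-4:], cols[:-4]
        seed_cols = proto_cols[-10:]
        pam_str = brute_rc_gapsafe("".join(aligned_t[c] for c in pam_cols))
    pam_ok = "-" not in pam_str and all(
        pam_str[i] in IUPAC["TTTV"[i]] for i in range(4)
    )
    mm = sum(aligned_t[c] != aligned_o[c] for c in proto_cols)
    seed_mm = sum(aligned_t[c] != aligned_o[c] for c in seed_cols)
    return mm, seed_mm, pam_ok, indel


def brute_rc_gapsafe(seq):
    return "".join({"A": "T", "C": "G", "G": "C", "T": "A", "-": "-"}.get(c, "N")
                   for c in reversed(seq))


class TestClassifyRuleTable:
    @staticmethod
    def stated_rule(cases):
        """Independent restatement: a species escapes iff PAM broken, indel,
        or >= 2 mismatches with >= 1 in the seed; lone 1-mismatch/0-seed
        offenders under intact PAM downgrade the verdict to unresolved."""
        offenders = [
            (pam, mm, seed) for pam, indel, mm, seed in cases
            if pam and not indel and not (mm >= 2 and seed >= 1)
        ]
        if not offenders:
            return "specific"
        if all(mm == 1 and seed == 0 for _, mm, seed in offenders):
            return "unresolved"
        return "cross_reactive"

    def test_full_rule_table_enumeration(self):
        """Every (pam, indel, mm<=3, seed<=mm) combination, 1-2 species."""
        combos = [
            (pam, indel, mm, seed)
            for pam in (True, False)
            for indel in (True, False)
            for mm in range(4)
            for seed in range(min(mm, 2) + 1)
        ]
        for case in combos:
            reports = [_report("x", *case)]
            assert classify_guide(reports) == self.stated_rule([case])
        for case_a, case_b in itertools.product(combos, repeat=2):
            reports = [_report("x", *case_a), _report("y", *case_b)]
            assert classify_guide(reports) == self.stated_rule([case_a, case_b])

    def test_all_pams_disrupted_is_specific(self):
        reports = [_report("x", False, False, 0, 0), _report("y", False, False, 0, 0)]
        assert classify_guide(reports) == "specific"

    def test_identical_window_is_cross_reactive(self):
        assert classify_guide([_report("x", True, False, 0, 0)]) == "cross_reactive"

    def test_single_nonseed_mismatch_is_unresolved(self):
        assert classify_guide([_report("x", True, False, 1, 0)]) == "unresolved"

    def test_monotone_in_divergence(self):
        """Adding mismatches or breaking a PAM never flips specific -> cross_reactive."""
        for pam in (True, False):
            for mm in range(4):
                for seed in range(min(mm, 2) + 1):
                    base = classify_guide([_report("x", pam, False, mm, seed)])
                    if base != "specific":
                        continue
                    worse = [
                        _report("x", False, False, mm, seed),
                        _report("x", pam, False, mm + 1, seed + 1),
                        _report("x", pam, True, mm, seed),
                    ]
                    for w in worse:
                        assert classify_guide([w]) != "cross_reactive"


def _report(sp, pam, indel, mm, seed):
    cross = pam and not indel and not (mm >= 2 and seed >= 1)
    return SpecificityReport(
        species=sp, pam_intact=pam, total_mismatches=mm, seed_mismatches=seed,
        indel_in_window=indel, cross_reactive=cross,
    )


class TestRanking:
    def _cand(self, verdict, pos, strand="+", gc=0.5, proto="ACGTC" * 4, margin=1):
        cand = GuideCandidate(
            guide_id=f"g{pos}{strand}", origin_species="a", region_label="VR1",
            strand=strand, pam_seq="TTTA", protospacer=proto,
            origin_interval=(pos, pos + 24), gc_fraction=gc,
        )
        cand.verdict = verdict
        cand.specificity = [_report("x", False, False, 2, margin - 2 if margin >= 2 else 0)]
        return cand

    def test_specific_ranks_before_cross_reactive(self):
        ranked = rank_candidates(
            [self._cand("cross_reactive", 0), self._cand("specific", 50)]
        )
        assert [c.verdict for c in ranked] == ["specific", "cross_reactive"]

    def test_position_breaks_ties(self):
        ranked = rank_candidates([self._cand("specific", 30), self._cand("specific", 10)])
        assert [c.origin_interval[0] for c in ranked] == [10, 30]

    def test_plus_strand_before_minus_at_same_position(self):
        ranked = rank_candidates(
            [self._cand("specific", 10, "-"), self._cand("specific", 10, "+")]
        )
        assert [c.strand for c in ranked] == ["+", "-"]

    def test_deterministic_total_order_on_random_sets(self, rng):
        import copy

        for _ in range(30):
            cands = [
                self._cand(
                    str(rng.choice(["specific", "unresolved", "cross_reactive"])),
                    int(rng.integers(0, 100)),
                    str(rng.choice(["+", "-"])),
                    float(rng.uniform(0, 1)),
                )
                for _ in range(int(rng.integers(2, 12)))
            ]
            a = rank_candidates(copy.deepcopy(cands))
            b = rank_candidates(copy.deepcopy(cands))
            assert [c.guide_id for c in a] == [c.guide_id for c in b]
            order = [(c.verdict, c.origin_interval, c.strand) for c in a]
            verdict_rank = [{"specific": 0, "unresolved": 1, "cross_reactive": 2}[v]
                            for v, _, _ in order]
            assert verdict_rank == sorted(verdict_rank)


class TestAntiStitch:
    def test_no_guide_overlaps_a_junction(self, rng):
        """The linker exists so no candidate spans the stitch between regions."""
        for seed in range(20):
            truth = generate_panel(
                PanelSpec(n_species=2 + seed % 3, rng_seed=1300 + seed)
            )
            msa = truth.msa
            profile = conservation_profile(msa)
            regions = find_variable_regions(profile, find_conserved_blocks(profile), msa)
            template = build_concatenated_template(regions, msa)
            guides = design_guides(template, msa)
            verify_guides(guides, template, msa)  # raises on violation
            # exhaustive template-coordinate check, independently of verify_guides
            seg_of = {(s.species, s.region_label): s for s in template.provenance}
            for g in guides:
                seg = seg_of[(g.origin_species, g.region_label)]
                t0 = seg.template_start + (g.origin_interval[0] - seg.local_start)
                t1 = t0 + 24
                assert all(t1 <= js or je <= t0 for js, je in template.junctions)
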