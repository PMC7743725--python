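"""Seed extraction, canonical k-mers, site scanning, near-targets, wobble, rc."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirselect import (
    AlphabetError,
    ConfigurationError,
    LengthError,
    UTRRecord,
    canonical_kmers,
    enumerate_near_targets,
    extract_seed,
    is_wobble_near_target,
    rc_background,
    revcomp_dna,
    scan_near_targets,
    scan_target_sites,
)
from mirselect.overlay import SNP
from mirselect.seqsites import dna_to_rna

rna_seeds = st.text(alphabet="ACGU", min_size=7, max_size=7)
dna_seqs = st.text(alphabet="ACGT", min_size=30, max_size=120)


class TestExtractSeed:
    @pytest.mark.parametrize(
        "mature,seed",
        [
            ("UGAGGUAGUAGGUUGUAUAGUU", "GAGGUAG"),
            ("UGAGGUAG", "GAGGUAG"),  # minimal length: the whole tail
        ],
    )
    def test_positions_two_to_eight(self, mature, seed):
        assert extract_seed(mature) == seed

    def test_too_short_raises(self):
        with pytest.raises(LengthError):
            extract_seed("UGAGGUA")

    def test_dna_alphabet_rejected(self):
        with pytest.raises(AlphabetError):
            extract_seed("TGAGGTAGT")


class TestCanonicalKmers:
    def test_let7_kmers(self):
        kmers = canonical_kmers("GAGGUAG")
        assert kmers == {"8mer": "CTACCTCA", "7mer-m8": "CTACCTC", "7mer-A1": "TACCTCA"}

    def test_homopolymer(self):
        assert canonical_kmers("AAAAAAA")["7mer-m8"] == "TTTTTTT"

    def test_wrong_length(self):
        with pytest.raises(LengthError):
            canonical_kmers("GAGGUA")

    @settings(deadline=None)
    @given(rna_seeds)
    def test_m8_reverse_complement_recovers_seed(self, seed):
        kmers = canonical_kmers(seed)
        assert dna_to_rna(revcomp_dna(kmers["7mer-m8"])) == seed
        assert kmers["8mer"] == kmers["7mer-m8"] + "A"
        assert kmers["7mer-A1"] == kmers["7mer-m8"][1:] + "A"


class TestScanTargetSites:
    def test_single_7mer_m8(self, toy_utr):
        sites = scan_target_sites(toy_utr, ["GAGGUAG"], {"7mer-m8"})
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end, s.site_type) == (3, 9, "7mer-m8")

    def test_hierarchy_collapses_to_8mer(self, toy_utr):
        sites = scan_target_sites(toy_utr, ["GAGGUAG"], {"8mer", "7mer-m8"})
        assert [(s.start, s.end, s.site_type) for s in sites] == [(3, 10, "8mer")]

    def test_no_match(self):
        utr = UTRRecord("T1", "G1", "GGGGGGGG")
        assert scan_target_sites(utr, ["GAGGUAG"]) == []

    def test_empty_family_list(self, toy_utr):
        with pytest.raises(ConfigurationError):
            scan_target_sites(toy_utr, [])

    def test_n_disqualifies_window(self):
        utr = UTRRecord("T1", "G1", "AACTACNTCAA")
        assert scan_target_sites(utr, ["GAGGUAG"]) == []

    def test_case_insensitive_load(self):
        utr = UTRRecord("T1", "G1", "aactacctcaa")
        assert len(scan_target_sites(utr, ["GAGGUAG"], {"7mer-m8"})) == 1

    def test_different_families_both_reported(self):
        # overlapping sites of two different families are reported independently
        utr = UTRRecord("T1", "G1", "AACTACCTCAA")
        other = dna_to_rna(revcomp_dna("ACTACCT"))  # family whose 7mer-m8 is ACTACCT
        sites = scan_target_sites(utr, ["GAGGUAG", other], {"7mer-m8"})
        assert {(s.family_id, s.start) for s in sites} == {("GAGGUAG", 3), (other, 2)}

    @settings(deadline=None, max_examples=30)
    @given(dna_seqs, rna_seeds)
    def test_round_trip_site_substring(self, seq, seed):
        utr = UTRRecord("T1", "G1", seq)
        kmers = canonical_kmers(seed)
        for s in scan_target_sites(utr, [seed]):
            assert utr.seq[s.start - 1 : s.end] == kmers[s.site_type]


class TestNearTargets:
    def test_count_and_membership(self):
        near = enumerate_near_targets("CTACCTC")
        assert len(near) == 21
        assert "CTACCTG" in near
        assert "CTACCTC" not in near

    def test_matches_exhaustive_enumeration(self):
        kmer = "CTACCTC"
        brute = {
            "".join(c)
            for c in itertools.product("ACGT", repeat=7)
            if sum(a != b for a, b in zip(c, kmer)) == 1
        }
        assert enumerate_near_targets(kmer) == brute

    def test_non_dna_rejected(self):
        with pytest.raises(AlphabetError):
            enumerate_near_targets("CUACCUC")


class TestWobble:
    @pytest.mark.parametrize(
        "site,variant,expected",
        [
            ("CTACCTC", "CTACCTT", True),   # variant U opposite seed G (miRNA pos 2)
            ("CTACCTC", "CTACCTA", False),  # A:G is not a wobble
        ],
    )
    def test_7mer_m8_pairs(self, site, variant, expected):
        assert is_wobble_near_target(site, variant, "GAGGUAG") is expected

    def test_wobble_at_seed_u(self):
        # variant G opposite seed U at miRNA position 6
        assert is_wobble_near_target("CTACCTC", "CTGCCTC", "GAGGUAG") is True

    def test_identical_kmers_rejected(self):
        with pytest.raises(ValueError):
            is_wobble_near_target("CTACCTC", "CTACCTC", "GAGGUAG")

    def test_a1_position_never_wobble(self):
        # substitution at the unpaired A1 adenosine of the 8mer
        assert is_wobble_near_target("CTACCTCA", "CTACCTCG", "GAGGUAG") is False

    def test_8mer_paired_region(self):
        # same substitution as the 7mer-m8 case, inside an 8mer
        assert is_wobble_near_target("CTACCTCA", "CTACCTTA", "GAGGUAG") is True


class TestRcBackground:
    def test_sequence_reverse_complement(self, toy_utr):
        rc_utr, _ = rc_background(toy_utr)
        assert rc_utr.seq == "TTGAGGTAGTT"

    def test_snp_mapping(self, toy_utr):
        snp = SNP("rs1", "T1", 9, "C", "G", global_freq=0.3)
        _, rc_snps = rc_background(toy_utr, [snp])
        s = rc_snps[0]
        assert (s.pos, s.ref_allele, s.alt_allele) == (3, "G", "C")
        assert s.global_freq == 0.3

    def test_involution(self, toy_utr):
        snp = SNP("rs1", "T1", 9, "C", "G", ancestral="alt", global_freq=0.3)
        rc_utr, rc_snps = rc_background(toy_utr, [snp])
        back_utr, back_snps = rc_background(rc_utr, rc_snps)
        assert back_utr.seq == toy_utr.seq
        assert back_snps[0] == snp

    def test_out_of_range_snp(self, toy_utr):
        with pytest.raises(ValueError):
            rc_background(toy_utr, [SNP("rs1", "T1", 99, "C", "G")])

    @settings(deadline=None, max_examples=25)
    @given(dna_seqs)
    def test_kmer_multiset_preserved(self, seq):
        k = 5
        utr = UTRRecord("T1", "G1", seq)
        rc_utr, _ = rc_background(utr)
        fwd = sorted(revcomp_dna(seq[i : i + k]) for i in range(len(seq) - k + 1))
        rev = sorted(rc_utr.seq[i : i + k] for i in range(len(seq) - k + 1))
        assert fwd == rev


class TestScanNearTargets:
    def test_window_count_and_fields(self):
        # CTACCTG is one substitution from the let-7 7mer-m8 CTACCTC
        utr = UTRRecord("T1", "G1", "AACTACCTGAA")
        windows = scan_near_targets(utr, "GAGGUAG")
        assert len(windows) == 1
        w = windows[0]
        assert (w.start, w.end, w.variant_kmer, w.diff_pos) == (3, 9, "CTACCTG", 7)
        assert w.wobble is False

    def test_site_itself_excluded(self):
        utr = UTRRecord("T1", "G1", "AACTACCTCAA")
        assert scan_near_targets(utr, "GAGGUAG") == []

    def test_wobble_flagged(self):
        utr = UTRRecord("T1", "G1", "AACTACCTTAA")  # U:G wobble at miRNA pos 2
        windows = scan_near_targets(utr, "GAGGUAG")
        assert windows and windows[0].wobble is True
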