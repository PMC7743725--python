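"""Target/near-target allele pairs: overlay, polarity, MAF filter, high-Fst table."""

import logging

import pytest

from mirselect import (
    ConfigurationError,
    SNP,
    UTRRecord,
    high_fst_table,
    maf_filter,
    overlay_snps,
    polarize,
    scan_target_sites,
)
from mirselect.io import load_high_fst_catalog
from mirselect.overlay import pairs_to_frame

SEED = "GAGGUAG"


def make_snp(pos, ref, alt, anc="unknown", gf=0.3, **freq):
    return SNP("rs1", "T1", pos, ref, alt, ancestral=anc, global_freq=gf, freq=freq)


class TestOverlay:
    def test_site_creating_snp(self, toy_utr):
        pairs = overlay_snps(toy_utr, [SEED], [make_snp(9, "C", "G")], {"7mer-m8"})
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.target_allele, p.nontarget_allele, p.window_start) == ("C", "G", 3)
        assert p.site_type == "7mer-m8"
        assert p.target_allele_freq["ALL"] == pytest.approx(0.7)

    def test_hierarchy_prefers_8mer_window(self, toy_utr):
        pairs = overlay_snps(toy_utr, [SEED], [make_snp(9, "C", "G")])
        assert pairs[0].site_type == "8mer"

    def test_snp_outside_windows_gives_no_pair(self, toy_utr):
        assert overlay_snps(toy_utr, [SEED], [make_snp(1, "A", "T")]) == []

    def test_both_alleles_sites_skipped(self):
        # seed AAAAAAA: with ref T the 7mer-m8 TTTTTTT covers position 8,
        # with alt A the 8mer TTTTTTTA does; both alleles are sites -> no pair
        utr = UTRRecord("T1", "G1", "TTTTTTTT")
        assert overlay_snps(utr, ["AAAAAAA"], [make_snp(8, "T", "A")]) == []

    def test_position_out_of_range(self, toy_utr):
        with pytest.raises(ValueError):
            overlay_snps(toy_utr, [SEED], [make_snp(99, "C", "G")])

    def test_wobble_flag_on_near_target(self, toy_utr):
        # nontarget window CTACCTT keeps a U:G wobble with the seed
        pairs = overlay_snps(toy_utr, [SEED], [make_snp(9, "C", "T")], {"7mer-m8"})
        assert pairs[0].wobble is True
        pairs = overlay_snps(toy_utr, [SEED], [make_snp(9, "C", "A")], {"7mer-m8"})
        assert pairs[0].wobble is False

    def test_creation_destruction_rescan(self, universe, universe_pairs):
        """Substituting the target allele creates a site; the nontarget allele removes it."""
        sense, _ = universe_pairs
        utr_by_id = {u.transcript_id: u for u in universe.utrs}
        families = sorted({m.family_id for m in universe.mirnas})
        snp_by_id = {s.snp_id: s for s in universe.snps}
        checked = 0
        for p in sense[:60]:
            utr = utr_by_id[p.transcript_id]
            snp = snp_by_id[p.snp_id]
            for allele, expect_site in ((p.target_allele, True), (p.nontarget_allele, False)):
                seq = utr.seq[: snp.pos - 1] + allele + utr.seq[snp.pos :]
                sites = scan_target_sites(UTRRecord(utr.transcript_id, utr.gene_id, seq),
                                          [p.family_id])
                covering = [s for s in sites if s.start <= snp.pos <= s.end]
                assert bool(covering) is expect_site
            checked += 1
        assert checked > 0


class TestPolarize:
    def test_target_derived(self, toy_utr):
        snp = make_snp(9, "C", "G", anc="alt", gf=0.7)  # ancestral G = nontarget
        pair = polarize(overlay_snps(toy_utr, [SEED], [snp])[0], snp)
        assert pair.polarity == "target-derived"
        assert pair.daf == pytest.approx(0.3)  # target C frequency = 1 - 0.7

    def test_target_ancestral(self, toy_utr):
        snp = make_snp(9, "C", "G", anc="ref", gf=0.7)  # ancestral C = target
        pair = polarize(overlay_snps(toy_utr, [SEED], [snp])[0], snp)
        assert pair.polarity == "target-ancestral"
        assert pair.daf == pytest.approx(0.7)

    def test_unknown_ancestral_unpolarized(self, toy_utr):
        snp = make_snp(9, "C", "G")
        pair = polarize(overlay_snps(toy_utr, [SEED], [snp])[0], snp)
        assert pair.polarity == "unpolarized"
        assert pair.daf is None

    def test_daf_complements_ancestral_frequency(self, toy_utr):
        snp = make_snp(9, "C", "G", anc="alt", gf=0.25)
        pair = polarize(overlay_snps(toy_utr, [SEED], [snp])[0], snp)
        anc_freq = 0.25  # ancestral allele is alt
        assert pair.daf + anc_freq == pytest.approx(1.0)


class TestMafFilter:
    def _pair(self, toy_utr, gf):
        snp = make_snp(9, "C", "G", gf=gf)
        return overlay_snps(toy_utr, [SEED], [snp])[0]

    @pytest.mark.parametrize("gf,kept", [(0.005, False), (0.01, True), (0.5, True),
                                         (0.995, False), (0.99, True)])
    def test_boundaries(self, toy_utr, gf, kept):
        pairs = [self._pair(toy_utr, gf)]
        assert (len(maf_filter(pairs)) == 1) is kept

    def test_idempotent(self, toy_utr):
        pairs = [self._pair(toy_utr, gf) for gf in (0.005, 0.2, 0.8, 0.999)]
        once = maf_filter(pairs)
        assert maf_filter(once) == once

    @pytest.mark.parametrize("bad", [0.0, -0.1, 0.6])
    def test_threshold_domain(self, toy_utr, bad):
        with pytest.raises(ConfigurationError):
            maf_filter([self._pair(toy_utr, 0.3)], threshold=bad)


class TestHighFstTable:
    def test_catalog_counts(self):
        pairs, fst = load_high_fst_catalog()
        table, (total, ancestral) = high_fst_table(pairs, fst, cutoff=0.6)
        assert total == 35
        assert ancestral == 21
        assert table["fst"].is_monotonic_decreasing

    def test_all_below_cutoff(self):
        pairs, fst = load_high_fst_catalog()
        table, counts = high_fst_table(pairs, fst * 0.5, cutoff=0.6)
        assert counts == (0, 0)
        assert table.empty

    def test_missing_fst_skipped_with_warning(self, caplog):
        pairs, fst = load_high_fst_catalog()
        short = fst.iloc[:-3]
        with caplog.at_level(logging.WARNING):
            _, (total, _) = high_fst_table(pairs, short, cutoff=0.6)
        assert total == 32
        assert any("Fst" in r.message for r in caplog.records)


def test_pairs_to_frame_columns(toy_utr):
    snp = make_snp(9, "C", "G", anc="alt", gf=0.7, EUR=0.6, AFR=0.9)
    pair = polarize(overlay_snps(toy_utr, [SEED], [snp])[0], snp)
    frame = pairs_to_frame([pair])
    assert frame.loc[0, "EUR"] == pytest.approx(0.4)  # target-allele frequency
    assert frame.loc[0, "polarity"] == "target-derived"
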