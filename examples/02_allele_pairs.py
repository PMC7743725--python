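"""Turn a SNP inside a target site into a polarized target/near-target pair.

When exactly one allele of a biallelic SNP completes a canonical site, the
SNP defines an allele pair: target allele vs near-target allele.  The
ancestral-allele annotation polarizes the pair (is the site the new or the
old state?) and gives the derived-allele frequency (DAF) analysed downstream.
"""

from mirselect import SNP, UTRRecord, overlay_snps, polarize, rc_background

utr = UTRRecord("ENST0001", "GENE1", "AACTACCTCAA")
snp = SNP("rs001", "ENST0001", pos=9, ref_allele="C", alt_allele="G",
          ancestral="alt", freq={"EUR": 0.2, "AFR": 0.45}, global_freq=0.3)

pair = overlay_snps(utr, ["GAGGUAG"], [snp])[0]
pair = polarize(pair, snp)
print(f"SNP {pair.snp_id}: target allele {pair.target_allele}, "
      f"near-target {pair.nontarget_allele} ({pair.site_type} at {pair.window_start})")
print(f"polarity: {pair.polarity}  DAF: {pair.daf:.2f}  wobble: {pair.wobble}")
print(f"target-allele frequencies: { {k: round(v, 2) for k, v in pair.target_allele_freq.items()} }")

rc_utr, rc_snps = rc_background(utr, [snp])
print(f"\nreverse-complement universe: {rc_utr.seq}, SNP mapped to pos "
      f"{rc_snps[0].pos} ({rc_snps[0].ref_allele}/{rc_snps[0].alt_allele})")
print("\nThe pair is 'target-derived': the site-creating allele is the new "
      "mutation, so a DAF shifted low means selection against the new site. "
      "The reverse-complement universe gives a composition-matched null.")
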