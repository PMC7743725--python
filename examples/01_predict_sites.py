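"""Scan a 3'-UTR for canonical microRNA target sites.

A seed family is the 7-nt sequence at positions 2-8 of the mature microRNA;
its canonical sites on the mRNA are the 8mer, 7mer-m8 and 7mer-A1 k-mers.
The scan reports every exact match, collapsing overlapping matches of one
family to the strongest site type.
"""

from mirselect import MicroRNA, UTRRecord, canonical_kmers, scan_target_sites

let7 = MicroRNA(name="let-7a-5p", mature="UGAGGUAGUAGGUUGUAUAGUU")
print(f"{let7.name}: seed {let7.family_id}")
for site_type, kmer in canonical_kmers(let7.family_id).items():
    print(f"  {site_type:8s} -> {kmer}")

utr = UTRRecord("ENST0001", "GENE1", "GGAACTACCTCAGGTTACCTCATTTCTACCTCTT")
sites = scan_target_sites(utr, [let7.family_id])
print(f"\n{len(sites)} site(s) in {utr.transcript_id} ({utr.length} nt):")
for s in sites:
    print(f"  {s.site_type:8s} at {s.start}-{s.end}: {utr.seq[s.start - 1:s.end]}")
print("\nEach line is one predicted microRNA binding site; an 8mer pairs the "
      "full seed plus an A opposite position 1 and is the strongest class.")
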