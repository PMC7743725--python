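"""Detect selection against novel target sites in a simulated universe.

The generator plants target/near-target SNP pairs in random UTRs and draws
derived-allele frequencies from a negatively selected spectrum (gamma = -10)
for derived target alleles of expressed families, neutral otherwise.  The
one-tailed KS test then compares coexpressed target-site DAFs against the
reverse-complement background: positive signed D = shift toward the
ancestral (non-target) allele.
"""

from mirselect import SimulationConfig, simulate_universe
from mirselect.pipeline import build_pairs, daf_analysis

universe = simulate_universe(SimulationConfig(rng_seed=7))
sense, background = build_pairs(universe.utrs, universe.mirnas, universe.snps,
                                maf_threshold=None)
print(f"{len(sense)} sense pairs, {len(background)} background pairs")

for polarity in ("target-derived", "target-ancestral"):
    frame = daf_analysis(
        sense, background, universe.mirnas, universe.tissue_contexts,
        tissues=["lung"], expression_table=universe.expression,
        min_class="moderate", polarity=polarity,
    )
    row = frame.iloc[0]
    print(f"{polarity:17s}: n={row.n_target:3d} vs {row.n_background:3d}  "
          f"D={row.D_signed:+.3f}  p={row.p_value:.2e}  q={row.q_value:.2e}")

print("\nOnly the target-derived comparison is significant: new target "
      "alleles are held at low frequency, while ancestral target sites show "
      "no comparable signal - the asymmetry built into the simulation.")
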