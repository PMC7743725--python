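# Methods

`mirselect` tests for selection on microRNA target sites segregating in
populations.  This note describes the model and procedure, the parameters
that matter, the synthetic-data generator, numerical choices, and known
limitations.

## Target sites and near-targets

Animal microRNA targeting is dominated by Watson–Crick pairing between the
*seed* (mature positions 2–8) and the 3′-UTR.  A seed family is the 7-nt seed
string itself; microRNAs with identical seeds recognise the same sites.  The
canonical site k-mers, written 5′→3′ on the mRNA so that the first base pairs
the seed's 3′-most base, are:

| type    | definition                                         | length |
|---------|----------------------------------------------------|--------|
| 7mer-m8 | reverse complement of the full seed (miRNA 2–8)    | 7      |
| 7mer-A1 | reverse complement of miRNA 2–7, followed by `A`   | 7      |
| 8mer    | 7mer-m8 followed by the A1 adenosine               | 8      |

The A1 adenosine is recognised directly by the silencing complex and pairs no
seed base.  Scanning is exact-match; overlapping matches of one family
collapse to the strongest type (8mer > 7mer-m8 > 7mer-A1, leftmost on ties),
and overlap grouping is by interval chaining, so a run of abutting matches of
one family yields a single site.  Overlapping sites of *different* families
are all reported.  Windows containing `N` never match; there is no IUPAC
expansion.  6mer sites (seed 2–7 only) are supported behind a flag and off by
default — they are weak and add mostly noise.  A *near-target* is any k-mer
at Hamming distance exactly 1 from a site k-mer (3k of them per site k-mer).

A near-target is a *wobble* near-target when the single substitution leaves a
G:U pair with the seed in the antiparallel duplex: variant `T` opposite seed
`G`, or variant `G` opposite seed `U`.  Position mapping follows the site
structure (k-mer position i pairs seed position 8−i for m8-anchored sites,
7−i for 7mer-A1; A1 substitutions can never be wobbles).  Wobble pairing
retains partial repression, so selection against the "non-target" allele is
expected to be weaker in the wobble subset.

## Allele pairs, polarity, and frequencies

A biallelic SNP inside a candidate window defines a target/near-target
*allele pair* when exactly one allele completes a canonical site of a family
in some window covering the SNP.  One pair is emitted per (SNP, family); if
several windows qualify, the strongest site type wins, then the leftmost
window (the data do not determine this choice; determinism does).  A SNP may
legitimately produce pairs for several families (a gain for one can be a loss
for another); each is analysed independently.  SNPs whose both alleles form
sites of the same family carry no contrast and are skipped, as are indels and
multiallelic records.

Input alt-allele frequencies are converted once to **target-allele
frequencies**.  The ancestral-allele annotation polarizes each pair:

* ancestral = near-target allele → **target-derived** (the site is the new
  state), DAF = target-allele frequency;
* ancestral = target allele → **target-ancestral** (the site is the old
  state), DAF = 1 − target-allele frequency;
* unknown/inconsistent → unpolarized: excluded from DAF analyses, retained
  for pooled Fst views.

Pairs pass a minor-allele-frequency filter (pooled MAF ≥ 1%, boundary
inclusive) before analysis.

## Null models and the DAF shift test

Two complementary backgrounds control for sequence composition and for the
absence of microRNA-mediated selection:

1. **Reverse-complement universe** — the identical overlay run on the
   reverse complement of each UTR (SNPs mapped to L − pos + 1 with
   complemented alleles; the transform is an involution).  Same length, same
   composition, no biological targeting.
2. **Zero-expression families** — sense-strand pairs of families whose every
   member microRNA has zero reads in every expression experiment for the
   tissue (a zero mean after rounding is not sufficient).

Per tissue, target-site DAFs of coexpressed pairs are compared to the
background by a one-tailed two-sample Kolmogorov–Smirnov test.  The signed
statistic follows the convention that **positive D means a shift toward the
ancestral allele** (low DAF): D⁺ = sup_x[F_target − F_background] is reported
as +D⁺ when testing that direction, and the opposite tail as −D⁻.  The
p-value is the one-sided asymptotic tail; by default Hodges' refinement

    p = exp(−2z² − 2z(m′ + 2n′) / (3·sqrt(m′n′(m′+n′)))),  z = D·sqrt(mn/(m+n))

with m′ ≥ n′ the sorted sample sizes.  The leading-term form
`exp(−2D²mn/(m+n))` is available via `corrected=False`; it was measured to be
visibly conservative at a few hundred observations per arm (mean null p
≈ 0.53), whereas the corrected form keeps null p-values close to uniform.
Residual conservativeness remains because DAFs live on the discrete i/n grid
and tie heavily at singleton frequencies; this makes the tests slightly
cautious, never anti-conservative.

Across the tissue family of tests, Benjamini–Hochberg q-values control the
FDR at 10%, with an additional discovery rule that the expected number of
false positives among the discoveries (q × number of discoveries at that
cutoff) stays below one.

## Expression and conservation context

MicroRNA abundance is the mean reads-per-million across experiments,
discretised as: 0 → none, (0, 50] → low, (50, 500] → moderate, (500, ∞) →
high.  The thresholds are strict ("more than 50", "more than 500"), so 50 RPM
is low and 500 is moderate.  A family's class is the maximum over its member
microRNAs — a site is avoided if *any* member carrying the seed is present.
Coexpressed pairs require the family at or above a minimum class (default
high; moderate for the broader analyses) and the transcript detected in the
tissue; transcript expression is binary because transcript levels are
themselves depressed by microRNA action.  Where tissue-specific
polyadenylation (APA) calls exist, an optional filter keeps only pairs whose
3′-UTR is experimentally supported in that tissue.

The joint effect of family expression class and seed-family conservation
class (primate / mammal / animal) on the DAF is assessed with a two-way
ANOVA on rank-transformed DAFs with interaction — the Scheirer–Ray–Hare
scheme.  Ranks use average ties; type-II sums of squares are computed by
nested least squares; each effect's statistic is
H = SS_effect / (SS_total/(N−1)), referred to χ² with the effect's df.  The
(high expression, animal conservation) cell is the intercept, and reported
coefficients are mean-rank differences of each cell from that intercept, so
more negative = stronger shift toward the ancestral non-target allele.  When
the response is constant all H are 0 and p = 1.

## Population differentiation

Nei's Gst-style Fst from per-population target-allele frequencies:
Hs = mean 2p(1−p), Ht = 2p̄(1−p̄) with p̄ the unweighted mean, Fst =
(Ht−Hs)/Ht (0 for a monomorphic locus).  Externally computed Fst values are
never recomputed — the estimator behind an imported table is generally
unknown.

Enrichment curves bin Fst into fixed intervals [0, w), …, [1−w, 1] (default
w = 0.05, last bin closed) and report log(Pt/Pb) (default base 10) where Pt
and Pb are the within-sample bin proportions of target-site and background
SNPs.  Bins with no background mass are flagged undefined rather than
infinite; an empty target bin over occupied background gives −inf.  The
high-Fst table lists pairs above a cutoff (default 0.6, strict), sorted by
Fst, annotated `a`/`d` for ancestral/derived target allele, with
per-superpopulation target-allele frequencies; the packaged catalog of 35
such SNPs reproduces the 35/21 split between gains and losses.

Two satellite analyses: a paired Wilcoxon signed-rank comparison of per-site
target-allele frequencies between two populations (zero differences dropped;
used when a derived seed variant of a microRNA spreads in one population),
and an OLS regression of target-allele frequency on absolute latitude
(slope, two-sided t-test, adjusted R²).  Populations with recent long-range
migration must be excluded by the caller before the latitude fit — their
sampling location no longer reflects their selective environment.

## Synthetic universes

The generator produces everything the pipeline reads, plus a truth table of
every planted object, all reproducible from one integer seed.

* **Sequences** — random UTRs at a set GC content (default 0.45, 40 UTRs of
  400 nt) and random 22-nt microRNAs with distinct seeds (default 18,
  cycling high / moderate / zero expression classes; conservation classes
  assigned at random).
* **Sites and SNPs** — site k-mers (7mer-m8 or 8mer) planted into free slots
  with 7-base flanks so windows never interact; one SNP per planted window.
  For the background universe the reverse complement of the k-mer is planted
  so that the reverse-complement transform recovers it.  Each placement is
  validated by running the real overlay on the candidate SNP in both
  universes and retried until exactly the intended pair (and nothing else)
  is produced, so truth labels are unambiguous; a universe that cannot fit
  the requested pairs raises a capacity error rather than degrading.
* **Frequencies** — DAFs are drawn from the stationary diffusion spectrum
  f(x) = (1 − e^{−2γ(1−x)}) / (x(1−x)(1 − e^{−2γ})) discretised to i/n
  (default n = 5008 chromosomes, a 1000-Genomes-scale haplotype sample),
  via `np.expm1` for stability (|γ| ≤ 50 routinely; guarded at 200).
  Selection (default γ = −10) applies only to sense-strand pairs where the
  derived allele is the target of an expressed (moderate/high) family; the
  ancestral-target and background arms are neutral, so the gain/loss
  asymmetry of the real analysis holds by construction.  An optional
  per-class γ map lets selection scale with expression class.  Frequencies
  are drawn rather than forward-simulated: a controlled effect size at
  desk-scale runtime.
* **Population structure** — per-population frequencies follow a
  Balding–Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F) around the pooled
  frequency (default F = 0.1, five populations); the expected Gst is
  F(1−1/K)/(1−F/K).

What the generator does **not** emulate: linkage and recombination, realistic
human demography, mutation-rate heterogeneity, overlapping or clustered
sites, 3′-compensatory pairing, and expression variation across experiments
beyond a ±20% jitter.  Passing tests therefore demonstrate correctness of
the machinery and its statistical calibration under the stated model — not
that real 3′-UTR data would show any particular effect size.

## Calibration and problem sizes

The test suite checks, at sizes chosen to keep a full run in well under a
minute per check on one core:

* null calibration — 200 neutral universes (150 pairs per arm) give
  one-tailed KS p-values consistent with uniformity; a balanced 3×3 null
  design (10 observations per cell, 2,000 replicates) holds the rank model's
  type-I error at 0.05 within the binomial 99% interval for all three
  effects;
* power — γ = −10 vs neutral at 500 pairs per arm is detected at p < 0.01 in
  ≥ 90/100 replicates;
* recovery — mean Nei Fst over 2,000 Balding–Nichols loci (K = 10, F = 0.1)
  falls in [0.08, 0.10];
* consistency — the truth table of a simulated universe is reproduced
  exactly (family, site type, window, polarity, DAF, wobble) by the overlay
  on the written files, and every emitted pair passes the
  site-creation/destruction re-scan.

## Known limitations

* Site scanning is exact-match seed pairing only; no thermodynamic scoring,
  bulges, or 3′-compensatory sites.  This deliberately mirrors a naive
  canonical-site predictor: it treats both alleles symmetrically, which
  reference-genome-anchored predictors cannot.
* The one-per-(SNP, family) rule with strongest-type/leftmost tie-breaking is
  a convention; real loci occasionally admit several defensible windows.
* The KS p-values are asymptotic (Hodges-corrected); exact small-sample
  computation is out of scope, and ties on the frequency grid make the tests
  slightly conservative.
* A SNP at the A1 position of an 8mer switches an 8mer to a 7mer-m8; both
  alleles then retain some targeting.  Window-level semantics classify this
  as a valid pair (the stronger site is "created"), which slightly dilutes
  the target/non-target contrast for such pairs.
* The latitude regression treats populations as independent points; shared
  demographic history is not modelled, so clines are suggestive, not causal.
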