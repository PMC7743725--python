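"""Synthetic universes with the statistical structure the analyses assume.

The generator builds everything the pipeline consumes — 3'-UTRs with planted
canonical sites, biallelic SNPs with known ancestral state, allele frequencies
drawn from neutral or negatively selected site-frequency spectra, per-tissue
expression tables — together with a truth table of every planted object, so
each stage can be tested end to end without external data.

Frequencies are drawn from the stationary diffusion site-frequency spectrum
f(x) = (1 - e^{-2 gamma (1-x)}) / (x (1-x) (1 - e^{-2 gamma})) discretised to
i/n for a finite sample of n chromosomes, rather than forward-simulated: this
gives a controlled effect size at desk-scale runtime.  Selection (gamma < 0)
is applied to pairs where the *derived* allele is the target site of an
expressed family; ancestral-target and background pairs are neutral, so the
gain/loss asymmetry seen in real populations is present by construction.
Multi-population frequencies follow a Balding-Nichols model: population
frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around the pooled frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigurationError
from .expression import TissueContext, annotate_expression, expression_class
from .overlay import SNP, SUPERPOPULATIONS, overlay_snps
from .seqsites import (
    MicroRNA,
    UTRRecord,
    canonical_kmers,
    is_wobble_near_target,
    rc_background,
    revcomp_dna,
)

#: the ten tissues analysed by default
TISSUES = (
    "lung", "blood", "placenta", "liver", "heart",
    "brain", "kidney", "cerebellum", "breast", "testis",
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic universe.

    ``n_chromosomes`` sets the frequency grid i/n (a 1000-Genomes-scale
    haplotype sample by default); ``gamma`` is the scaled selection
    coefficient applied to derived target alleles of expressed families
    (negative = deleterious); ``F`` drives Balding-Nichols population
    differentiation across ``n_populations`` populations.
    """

    rng_seed: int
    n_utrs: int = 40
    utr_length: int = 400
    gc_content: float = 0.45
    n_mirnas: int = 18
    n_chromosomes: int = 5008
    gamma: float = -10.0
    F: float = 0.1
    n_populations: int = 5
    tissues: tuple = TISSUES
    n_target_pairs: int = 150
    n_background_pairs: int = 150
    frac_target_derived: float = 0.5
    frac_unpolarized: float = 0.0
    experiments_per_tissue: int = 3
    gamma_by_class: dict | None = None

    def __post_init__(self) -> None:
        for name in ("n_utrs", "utr_length", "n_mirnas", "n_chromosomes", "n_populations"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigurationError("gc_content must lie in (0,1)")
        if not 0.0 < self.F < 1.0:
            raise ConfigurationError("F must lie in (0,1)")
        if self.n_mirnas < 3:
            raise ConfigurationError("need at least 3 microRNAs (one per expression class)")


@dataclass
class SimulatedUniverse:
    config: SimulationConfig
    utrs: list
    mirnas: list
    snps: list
    expression: pd.DataFrame
    tissue_contexts: dict
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# site-frequency spectra
# ---------------------------------------------------------------------------

def sfs_neutral(n: int) -> np.ndarray:
    """Neutral spectrum over derived counts 1..n-1: P(i) proportional to 1/i."""
    if n < 2:
        raise ConfigurationError("sample size n must be >= 2")
    i = np.arange(1, n, dtype=float)
    p = 1.0 / i
    return p / p.sum()


def sfs_selected(n: int, gamma: float) -> np.ndarray:
    """Stationary spectrum under genic selection with scaled coefficient gamma.

    Evaluates f(x) = (1 - e^{-2 gamma (1-x)}) / (x (1-x) (1 - e^{-2 gamma}))
    at x = i/n and normalises.  Deleterious gamma (< 0) piles mass onto rare
    derived alleles.  Stable for |gamma| <= 50; use :func:`sfs_neutral` for
    gamma = 0.
    """
    if n < 2:
        raise ConfigurationError("sample size n must be >= 2")
    if gamma == 0.0:
        raise ConfigurationError("gamma must be non-zero; use sfs_neutral for gamma = 0")
    if abs(gamma) > 200:
        raise ConfigurationError(f"|gamma| = {abs(gamma)} too extreme; overflow guard at 200")
    x = np.arange(1, n, dtype=float) / n
    with np.errstate(over="raise"):
        num = np.expm1(-2.0 * gamma * (1.0 - x))
        den = x * (1.0 - x) * np.expm1(-2.0 * gamma)
    p = num / den
    if (p < 0).any() or not np.isfinite(p).all():
        raise FloatingPointError("unstable spectrum; reduce |gamma|")
    return p / p.sum()


def sample_dafs(rng: np.random.Generator, spectrum: np.ndarray, size: int) -> np.ndarray:
    """Draw derived-allele frequencies i/n from a discretised spectrum."""
    n = spectrum.size + 1
    counts = rng.choice(np.arange(1, n), size=size, p=spectrum)
    return counts / n


# ---------------------------------------------------------------------------
# Balding-Nichols multi-population frequencies
# ---------------------------------------------------------------------------

def balding_nichols(
    rng: np.random.Generator, p_bar: float, F: float, k: int
) -> np.ndarray:
    """K population frequencies around a pooled frequency under drift F."""
    if not 0.0 < F < 1.0:
        raise ConfigurationError("F must lie in (0,1)")
    p_bar = min(max(p_bar, 1e-9), 1.0 - 1e-9)
    a = p_bar * (1.0 - F) / F
    b = (1.0 - p_bar) * (1.0 - F) / F
    return rng.beta(a, b, size=k)


def simulate_fst_loci(
    config: SimulationConfig,
    p_bar_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    n_loci: int = 1000,
) -> np.ndarray:
    """Per-locus per-population frequencies under the Balding-Nichols model.

    Returns an (n_loci, n_populations) array.  ``p_bar_sampler(rng, n)`` draws
    the pooled frequencies; the default is uniform on [0.1, 0.9].
    """
    rng = np.random.default_rng(config.rng_seed)
    if p_bar_sampler is None:
        p_bars = rng.uniform(0.1, 0.9, size=n_loci)
    else:
        p_bars = np.asarray(p_bar_sampler(rng, n_loci), dtype=float)
    out = np.empty((n_loci, config.n_populations))
    for i, pb in enumerate(p_bars):
        out[i] = balding_nichols(rng, float(pb), config.F, config.n_populations)
    return out


# ---------------------------------------------------------------------------
# universe generation
# ---------------------------------------------------------------------------

def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=length, p=probs))


def _make_mirnas(rng: np.random.Generator, config: SimulationConfig) -> tuple[list, dict]:
    """Random mature microRNAs with distinct seeds; class cycles high/moderate/none."""
    mirnas: list[MicroRNA] = []
    classes: dict[str, str] = {}
    cycle = ("high", "moderate", "none")
    seeds_seen: set[str] = set()
    i = 0
    while len(mirnas) < config.n_mirnas:
        mature = _random_rna(rng, 22)
        seed = mature[1:8]
        if seed in seeds_seen:
            continue
        seeds_seen.add(seed)
        name = f"sim-miR-{i + 1}"
        cons = ("primate", "mammal", "animal")[int(rng.integers(3))]
        mirnas.append(MicroRNA(name=name, mature=mature, conservation=cons))
        classes[seed] = cycle[i % 3]
        i += 1
    return mirnas, classes


def _make_expression(
    rng: np.random.Generator, config: SimulationConfig, mirnas: Sequence[MicroRNA],
    classes: dict,
) -> pd.DataFrame:
    rows = []
    for m in mirnas:
        cls = classes[m.family_id]
        for tissue in config.tissues:
            if cls == "high":
                base = rng.uniform(700.0, 4000.0)
            elif cls == "moderate":
                base = rng.uniform(80.0, 380.0)
            else:
                base = 0.0
            for e in range(config.experiments_per_tissue):
                rpm = 0.0 if base == 0.0 else base * rng.uniform(0.8, 1.2)
                rows.append({"mirna": m.name, "tissue": tissue,
                             "experiment": f"exp{e + 1}", "rpm": rpm})
    return pd.DataFrame(rows)


class _Occupancy:
    """Free-interval bookkeeping per UTR; planted windows keep 7-base flanks."""

    def __init__(self, length: int, margin: int = 7) -> None:
        self.length = length
        self.margin = margin
        self.taken: list[tuple[int, int]] = []

    def fits(self, start: int, end: int) -> bool:
        lo, hi = start - self.margin, end + self.margin
        if start < 1 or end > self.length:
            return False
        return all(hi < s or lo > e for s, e in self.taken)

    def reserve(self, start: int, end: int) -> None:
        self.taken.append((start - self.margin, end + self.margin))


def _plant_pair(
    rng: np.random.Generator,
    config: SimulationConfig,
    seqs: dict,
    occ: dict,
    genes: dict,
    seeds: list[str],
    classes: dict,
    universe: str,
    snp_id: str,
    max_tries: int = 200,
):
    """Plant one site window plus a SNP; returns (SNP, truth-row) or None.

    All writes happen in sense coordinates; for the reverse-complement
    universe the window content is the reverse complement of the site k-mer
    and the truth row is expressed in that universe's frame.  Placement is
    validated by running the real overlay on the candidate SNP in both
    universes and requiring exactly the intended pair (and nothing on the
    other strand), so truth labels are unambiguous.
    """
    n = config.n_chromosomes
    neutral = sfs_neutral(n)
    for _ in range(max_tries):
        family = seeds[int(rng.integers(len(seeds)))]
        site_type = "7mer-m8" if rng.random() < 0.6 else "8mer"
        kmer = canonical_kmers(family)[site_type]
        k = len(kmer)
        tid = list(seqs)[int(rng.integers(len(seqs)))]
        L = len(seqs[tid])
        if L < k + 2:
            continue
        u_start = int(rng.integers(2, L - k))  # universe-frame start, 1-based
        if universe == "sense":
            s_start, s_end = u_start, u_start + k - 1
        else:
            s_start, s_end = L - (u_start + k - 1) + 1, L - u_start + 1
        if not occ[tid].fits(s_start, s_end):
            continue

        content = kmer if universe == "sense" else revcomp_dna(kmer)
        old = seqs[tid][s_start - 1 : s_end]
        seqs[tid][s_start - 1 : s_end] = list(content)
        # pin the site type: for a planted 7mer-m8, an adjacent A would
        # silently upgrade it to an 8mer
        old_flank = None
        if site_type == "7mer-m8":
            if universe == "sense":
                fpos = s_end  # 0-based index of base after the window
                if fpos < L and seqs[tid][fpos] == "A":
                    old_flank = (fpos, "A")
                    seqs[tid][fpos] = "C"
            else:
                fpos = s_start - 2  # base before the window on the sense strand
                if fpos >= 0 and seqs[tid][fpos] == "T":
                    old_flank = (fpos, "T")
                    seqs[tid][fpos] = "G"

        offset = int(rng.integers(k))  # 0-based offset within the window
        u_pos = u_start + offset
        s_pos = u_pos if universe == "sense" else L - u_pos + 1
        u_target = kmer[offset]
        u_nontarget = "ACGT".replace(u_target, "")[int(rng.integers(3))]
        s_target = u_target if universe == "sense" else _COMP[u_target]
        s_nontarget = u_nontarget if universe == "sense" else _COMP[u_nontarget]

        roll = rng.random()
        if roll < config.frac_unpolarized:
            polarity = "unpolarized"
        elif roll < config.frac_unpolarized + config.frac_target_derived:
            polarity = "target-derived"
        else:
            polarity = "target-ancestral"
        fam_class = classes[family]
        # selection acts only on real (sense-strand) sites gained by the
        # derived allele; the reverse-complement universe is neutral
        gamma_eff = 0.0
        if universe == "sense" and polarity == "target-derived":
            if config.gamma_by_class is not None:
                gamma_eff = config.gamma_by_class.get(fam_class, 0.0)
            elif fam_class in ("moderate", "high"):
                gamma_eff = config.gamma
        spectrum = neutral if gamma_eff == 0.0 else sfs_selected(n, gamma_eff)
        daf = float(sample_dafs(rng, spectrum, 1)[0])
        if polarity == "target-derived":
            target_freq = daf
        elif polarity == "target-ancestral":
            target_freq = 1.0 - daf
        else:
            target_freq = daf  # frequency drawn neutrally; no polarity meaning

        # reference allele = the base actually written in the FASTA
        ref_is_target = rng.random() < 0.5
        s_ref = s_target if ref_is_target else s_nontarget
        s_alt = s_nontarget if ref_is_target else s_target
        seqs[tid][s_pos - 1] = s_ref
        alt_freq = target_freq if s_alt == s_target else 1.0 - target_freq
        if polarity == "unpolarized":
            ancestral = "unknown"
        elif polarity == "target-derived":
            ancestral = "ref" if s_ref == s_nontarget else "alt"
        else:
            ancestral = "ref" if s_ref == s_target else "alt"
        pop_freqs = balding_nichols(rng, alt_freq, config.F, config.n_populations)
        pops = list(SUPERPOPULATIONS[: config.n_populations])
        if config.n_populations > len(SUPERPOPULATIONS):
            pops += [f"POP{j}" for j in range(len(SUPERPOPULATIONS), config.n_populations)]
        snp = SNP(
            snp_id=snp_id, transcript_id=tid, pos=s_pos,
            ref_allele=s_ref, alt_allele=s_alt, ancestral=ancestral,
            freq={pop: float(f) for pop, f in zip(pops, pop_freqs)},
            global_freq=alt_freq,
        )

        utr = UTRRecord(tid, genes[tid], "".join(seqs[tid]))
        sense_pairs = overlay_snps(utr, seeds, [snp])
        rc_utr, rc_snps = rc_background(utr, [snp])
        rc_pairs = overlay_snps(rc_utr, seeds, rc_snps, universe="revcomp-background")
        want, other = (sense_pairs, rc_pairs) if universe == "sense" else (rc_pairs, sense_pairs)
        ok = (
            len(other) == 0
            and len(want) == 1
            and want[0].family_id == family
            and want[0].site_type == site_type
            and want[0].window_start == u_start
            and want[0].target_allele == u_target
        )
        if not ok:
            seqs[tid][s_start - 1 : s_end] = old  # roll back and retry
            if old_flank is not None:
                seqs[tid][old_flank[0]] = old_flank[1]
            continue
        occ[tid].reserve(s_start, s_end)
        variant = kmer[:offset] + u_nontarget + kmer[offset + 1 :]
        truth = {
            "snp_id": snp_id, "universe": universe, "transcript_id": tid,
            "family_id": family, "site_type": site_type, "window_start": u_start,
            "pos": u_pos, "target_allele": u_target, "nontarget_allele": u_nontarget,
            "polarity": polarity, "daf": daf if polarity != "unpolarized" else float("nan"),
            "target_freq": target_freq, "family_class": fam_class,
            "gamma": gamma_eff, "selected": gamma_eff != 0.0,
            "wobble": is_wobble_near_target(kmer, variant, family),
        }
        return snp, truth
    return None


def simulate_universe(config: SimulationConfig) -> SimulatedUniverse:
    """Generate a fully synthetic, reproducible analysis universe.

    Returns UTRs, microRNAs (with expression and conservation filled in),
    SNPs in sense coordinates, the long-format expression table, per-tissue
    contexts (all transcripts detected; a random subset with APA evidence) and
    the truth table of every planted target/near-target pair.
    """
    rng = np.random.default_rng(config.rng_seed)
    mirnas, classes = _make_mirnas(rng, config)
    seeds = [m.family_id for m in mirnas]
    expression = _make_expression(rng, config, mirnas, classes)
    annotate_expression(mirnas, expression)

    utr_ids = [f"T{i + 1:04d}" for i in range(config.n_utrs)]
    genes = {tid: f"G{i + 1:04d}" for i, tid in enumerate(utr_ids)}
    seqs = {tid: _random_dna(rng, config.utr_length, config.gc_content) for tid in utr_ids}
    occ = {tid: _Occupancy(config.utr_length) for tid in utr_ids}

    snps: list[SNP] = []
    truth_rows: list[dict] = []
    plan = [("sense", config.n_target_pairs), ("revcomp-background", config.n_background_pairs)]
    counter = 0
    for universe, n_pairs in plan:
        for _ in range(n_pairs):
            counter += 1
            planted = _plant_pair(
                rng, config, seqs, occ, genes, seeds, classes, universe,
                snp_id=f"s{counter:06d}",
            )
            if planted is None:
                raise CapacityError(
                    f"could not place pair {counter}: universe too small for "
                    f"{config.n_target_pairs}+{config.n_background_pairs} pairs"
                )
            snps.append(planted[0])
            truth_rows.append(planted[1])

    utrs = [UTRRecord(tid, genes[tid], "".join(seqs[tid])) for tid in utr_ids]
    contexts = {}
    for tissue in config.tissues:
        apa = {tid for tid in utr_ids if rng.random() < 0.6}
        contexts[tissue] = TissueContext(
            tissue=tissue, expressed_transcripts=set(utr_ids), apa_transcripts=apa
        )
    truth = pd.DataFrame(truth_rows)
    return SimulatedUniverse(
        config=config, utrs=utrs, mirnas=mirnas, snps=snps,
        expression=expression, tissue_contexts=contexts, truth=truth,
    )
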