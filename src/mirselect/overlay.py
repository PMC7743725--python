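"""Overlay of biallelic SNPs on the target-site universe.

A SNP inside a potential site window splits the population into two allelic
sequences.  When exactly one allele completes a canonical site k-mer for a
seed family, the SNP defines a *target/near-target allele pair*: one allele is
a target site, the other is one substitution away.  Pairs are polarized by the
ancestral-allele annotation (target-derived when the target allele is the new
one, target-ancestral when it is the old one), and allele frequencies are
re-expressed as target-allele and derived-allele frequencies (DAF).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError
from .seqsites import (
    SITE_TYPES,
    _SITE_RANK,
    MicroRNA,
    UTRRecord,
    _normalize_families,
    canonical_kmers,
    is_wobble_near_target,
)

logger = logging.getLogger(__name__)

POLARITIES = ("target-derived", "target-ancestral", "unpolarized")

#: 1000 Genomes superpopulation labels plus the pooled column.
SUPERPOPULATIONS = ("EAS", "AMR", "AFR", "EUR", "SAS")
ALL_POPULATION = "ALL"


@dataclass
class SNP:
    """A biallelic SNP located on a 3'-UTR (1-based UTR coordinates).

    ``freq`` maps population label -> alt-allele frequency; ``global_freq`` is
    the pooled alt-allele frequency.  ``ancestral`` says which allele is the
    inferred ancestral state ('ref', 'alt', or 'unknown').
    """

    snp_id: str
    transcript_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    ancestral: str = "unknown"
    freq: dict = field(default_factory=dict)
    global_freq: float = float("nan")

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"SNP {self.snp_id!r}: alleles must be single bases")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.snp_id!r}: ref and alt alleles identical")
        if self.ancestral not in ("ref", "alt", "unknown"):
            raise ValueError(f"SNP {self.snp_id!r}: ancestral must be ref/alt/unknown")
        for label, f in list(self.freq.items()) + [("global", self.global_freq)]:
            if f == f and not 0.0 <= f <= 1.0:  # NaN-tolerant
                raise ValueError(f"SNP {self.snp_id!r}: frequency {label}={f} outside [0,1]")

    def ancestral_base(self) -> str | None:
        if self.ancestral == "ref":
            return self.ref_allele
        if self.ancestral == "alt":
            return self.alt_allele
        return None


@dataclass
class AlleleTargetPair:
    """A SNP whose two alleles split into a target site and a near-target.

    ``target_allele_freq`` maps population label (including 'ALL') to the
    frequency of the site-creating allele.  ``daf`` is the derived-allele
    frequency, present only when the pair is polarized; for target-derived
    pairs daf equals the target-allele frequency, for target-ancestral pairs
    its complement.  ``wobble`` flags near-targets that keep a G:U pair.
    """

    snp_id: str
    transcript_id: str
    family_id: str
    window_start: int
    site_type: str
    target_allele: str
    nontarget_allele: str
    polarity: str = "unpolarized"
    target_allele_freq: dict = field(default_factory=dict)
    daf: float | None = None
    wobble: bool = False
    universe: str = "sense"

    @property
    def global_target_freq(self) -> float:
        return self.target_allele_freq.get(ALL_POPULATION, float("nan"))


def _window_candidates(utr: UTRRecord, snp: SNP, kmers: Mapping[str, str],
                       site_types: Iterable[str]) -> dict[str, list[tuple[str, int]]]:
    """For each allele, the (site_type, window_start) windows forming a site."""
    hits: dict[str, list[tuple[str, int]]] = {snp.ref_allele: [], snp.alt_allele: []}
    L = utr.length
    for st in site_types:
        kmer = kmers[st]
        k = len(kmer)
        lo = max(1, snp.pos - k + 1)
        hi = min(snp.pos, L - k + 1)
        for start in range(lo, hi + 1):
            window = utr.seq[start - 1 : start - 1 + k]
            offset = snp.pos - start
            for allele in (snp.ref_allele, snp.alt_allele):
                if window[:offset] + allele + window[offset + 1 :] == kmer:
                    hits[allele].append((st, start))
    return hits


def overlay_snps(
    utr: UTRRecord,
    families: Iterable,
    snps: Sequence[SNP],
    site_types: Iterable[str] = SITE_TYPES,
    universe: str = "sense",
) -> list[AlleleTargetPair]:
    """Build target/near-target allele pairs for SNPs on one UTR.

    For every SNP and seed family, each window of site width covering the SNP
    is evaluated under both alleles; a pair is emitted when exactly one allele
    forms a canonical site anywhere in those windows.  If several windows
    qualify for the same family the strongest site type wins, then the
    leftmost window.  SNPs whose two alleles both form sites of the same
    family carry no target/near-target contrast and are skipped.
    """
    fams = _normalize_families(families)
    if not fams:
        raise ConfigurationError("empty family list")
    site_types = sorted(set(site_types), key=lambda t: _SITE_RANK.get(t, 99))
    pairs: list[AlleleTargetPair] = []
    for snp in snps:
        if not 1 <= snp.pos <= utr.length:
            raise ValueError(
                f"SNP {snp.snp_id!r} position {snp.pos} outside UTR "
                f"{utr.transcript_id!r} (length {utr.length})"
            )
        if snp.transcript_id and snp.transcript_id != utr.transcript_id:
            continue
        for family_id, seed in fams.items():
            kmers = canonical_kmers(seed, include_6mer="6mer" in site_types)
            hits = _window_candidates(utr, snp, kmers, site_types)
            ref_hits, alt_hits = hits[snp.ref_allele], hits[snp.alt_allele]
            if ref_hits and alt_hits:
                continue  # both alleles are sites of this family: no contrast
            if not ref_hits and not alt_hits:
                continue
            target_allele = snp.ref_allele if ref_hits else snp.alt_allele
            nontarget_allele = snp.alt_allele if ref_hits else snp.ref_allele
            st, start = min(
                ref_hits or alt_hits, key=lambda h: (_SITE_RANK.get(h[0], 99), h[1])
            )
            kmer = kmers[st]
            offset = snp.pos - start
            window = utr.seq[start - 1 : start - 1 + len(kmer)]
            variant = window[:offset] + nontarget_allele + window[offset + 1 :]
            try:
                wobble = is_wobble_near_target(kmer, variant, seed)
            except ValueError:
                wobble = False
            alt_freqs = dict(snp.freq)
            alt_freqs[ALL_POPULATION] = snp.global_freq
            if target_allele == snp.alt_allele:
                tfreq = alt_freqs
            else:
                tfreq = {pop: 1.0 - f for pop, f in alt_freqs.items()}
            pairs.append(
                AlleleTargetPair(
                    snp_id=snp.snp_id,
                    transcript_id=utr.transcript_id,
                    family_id=family_id,
                    window_start=start,
                    site_type=st,
                    target_allele=target_allele,
                    nontarget_allele=nontarget_allele,
                    target_allele_freq=tfreq,
                    wobble=wobble,
                    universe=universe,
                )
            )
    pairs.sort(key=lambda p: (p.transcript_id, p.window_start, p.snp_id, p.family_id))
    return pairs


def polarize(pair: AlleleTargetPair, snp: SNP) -> AlleleTargetPair:
    """Assign ancestral polarity and derived-allele frequency to a pair.

    Ancestral == near-target allele -> the site is the new state
    (target-derived, daf = target-allele frequency).  Ancestral == target
    allele -> the site is the old state (target-ancestral, daf = 1 - target
    frequency).  Unknown or inconsistent ancestral states leave the pair
    unpolarized, which excludes it from DAF analyses.
    """
    anc = snp.ancestral_base()
    tfreq = pair.global_target_freq
    if anc == pair.nontarget_allele:
        polarity, daf = "target-derived", tfreq
    elif anc == pair.target_allele:
        polarity, daf = "target-ancestral", 1.0 - tfreq
    else:
        polarity, daf = "unpolarized", None
    return dataclasses.replace(pair, polarity=polarity, daf=daf)


def maf_filter(pairs: Sequence[AlleleTargetPair], threshold: float = 0.01) -> list[AlleleTargetPair]:
    """Keep pairs whose pooled minor-allele frequency is >= threshold.

    Mirrors the convention of analysing only segregating sites where the minor
    allele reaches at least 1% of the sampled population.
    """
    if not 0.0 < threshold <= 0.5:
        raise ConfigurationError(f"MAF threshold {threshold} outside (0, 0.5]")
    kept = []
    for p in pairs:
        f = p.global_target_freq
        if f == f and min(f, 1.0 - f) >= threshold:
            kept.append(p)
    return kept


def pairs_to_frame(pairs: Sequence[AlleleTargetPair]) -> pd.DataFrame:
    """Tabulate pairs; per-population target-allele frequencies become columns."""
    pops: list[str] = []
    for p in pairs:
        for pop in p.target_allele_freq:
            if pop not in pops:
                pops.append(pop)
    rows = []
    for p in pairs:
        row = {
            "snp_id": p.snp_id,
            "transcript_id": p.transcript_id,
            "family_id": p.family_id,
            "window_start": p.window_start,
            "site_type": p.site_type,
            "target_allele": p.target_allele,
            "nontarget_allele": p.nontarget_allele,
            "polarity": p.polarity,
            "daf": p.daf,
            "wobble": p.wobble,
            "universe": p.universe,
        }
        for pop in pops:
            row[pop] = p.target_allele_freq.get(pop, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def high_fst_table(
    pairs,
    fst: Mapping[str, float] | pd.Series,
    cutoff: float = 0.6,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Target-site SNPs with Fst above a cutoff, most differentiated first.

    ``pairs`` may be a list of :class:`AlleleTargetPair` or a DataFrame with at
    least ``snp_id`` and ``polarity`` columns (plus per-population target-allele
    frequency columns).  Each retained row is annotated ``target_state`` 'a'
    (target allele ancestral) or 'd' (derived); unpolarized pairs get '?'.
    Returns the table and the counts ``(total, target_ancestral)``.
    """
    frame = pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)
    fst = pd.Series(dict(fst)) if not isinstance(fst, pd.Series) else fst
    frame = frame.copy()
    missing = ~frame["snp_id"].isin(fst.index)
    if missing.any():
        logger.warning(
            "no Fst for %d SNP(s), e.g. %s; rows skipped",
            int(missing.sum()),
            frame.loc[missing, "snp_id"].iloc[0],
        )
        frame = frame[~missing]
    frame["fst"] = frame["snp_id"].map(fst)
    if ((frame["fst"] < 0) | (frame["fst"] > 1)).any():
        raise ValueError("Fst values outside [0,1]")
    table = frame[frame["fst"] > cutoff].sort_values("fst", ascending=False)
    state = {"target-ancestral": "a", "target-derived": "d", "unpolarized": "?"}
    table = table.assign(target_state=table["polarity"].map(state))
    n_total = len(table)
    n_ancestral = int((table["target_state"] == "a").sum())
    return table.reset_index(drop=True), (n_total, n_ancestral)
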