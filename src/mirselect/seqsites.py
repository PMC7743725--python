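"""Seed-match target-site prediction on 3'-UTR sequences.

MicroRNA targeting in animals is dominated by Watson-Crick pairing between the
microRNA *seed* (nucleotides 2-8 of the mature sequence) and the 3'-UTR of the
transcript.  This module derives seeds, builds the canonical site k-mers
(8mer, 7mer-m8, 7mer-A1), scans UTRs for exact site matches, enumerates
*near-targets* (sequences one substitution away from a site), classifies
near-targets that retain a G:U wobble pair with the seed, and constructs the
reverse-complement background universe used as a length- and
composition-matched null.

Coordinates in all public contracts are 1-based and inclusive, matching VCF
conventions.  UTR sequences are DNA (U normalized to T on load); microRNA
sequences and seeds stay in the RNA alphabet, and conversions are explicit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import AlphabetError, ConfigurationError, LengthError

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

#: Canonical site types, strongest first.
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

#: Weak single-heptamer match of seed nucleotides 2-7 only; off by default.
SITE_TYPE_6MER = "6mer"

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CONSERVATION_CLASSES = ("primate", "mammal", "animal", "unknown")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MicroRNA:
    """A mature microRNA with its seed family and annotation.

    ``family_id`` is the 7-nt seed itself (positions 2-8 of the mature
    sequence): microRNAs sharing a seed belong to one family and recognise the
    same canonical sites.  ``expression`` maps tissue -> mean reads-per-million.
    """

    name: str
    mature: str
    family_id: str = ""
    conservation: str = "unknown"
    expression: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mature = self.mature.upper().replace("T", "U")
        if len(self.mature) < 8:
            raise LengthError(f"mature sequence of {self.name!r} shorter than 8 nt")
        if not set(self.mature) <= RNA_ALPHABET:
            raise AlphabetError(f"non-RNA characters in mature sequence of {self.name!r}")
        if not self.family_id:
            self.family_id = extract_seed(self.mature)
        elif self.family_id != extract_seed(self.mature):
            raise ValueError(f"family_id of {self.name!r} is not the seed of its mature sequence")
        if self.conservation not in CONSERVATION_CLASSES:
            raise ValueError(f"unknown conservation class {self.conservation!r}")


@dataclass
class UTRRecord:
    """A 3'-UTR sequence on the sense strand, DNA alphabet."""

    transcript_id: str
    gene_id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if not self.seq:
            raise LengthError(f"empty UTR sequence for {self.transcript_id!r}")
        if not set(self.seq) <= DNA_ALPHABET | {"N"}:
            raise AlphabetError(f"non-DNA characters in UTR {self.transcript_id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TargetSite:
    """A located canonical seed-match site on a UTR (1-based inclusive)."""

    transcript_id: str
    start: int
    end: int
    family_id: str
    site_type: str
    universe: str = "sense"


@dataclass(frozen=True)
class NearTargetWindow:
    """A window exactly one substitution away from a canonical site k-mer."""

    transcript_id: str
    start: int
    end: int
    family_id: str
    variant_kmer: str
    diff_pos: int
    wobble: bool


# ---------------------------------------------------------------------------
# sequence primitives
# ---------------------------------------------------------------------------

def revcomp_dna(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT plus N)."""
    if not set(seq) <= DNA_ALPHABET | {"N"}:
        raise AlphabetError(f"non-DNA characters in {seq!r}")
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def extract_seed(mature: str) -> str:
    """Seed = mature microRNA positions 2-8 (1-based), RNA alphabet.

    >>> extract_seed("UGAGGUAGUAGGUUGUAUAGUU")
    'GAGGUAG'
    """
    mature = mature.upper()
    if not set(mature) <= RNA_ALPHABET:
        raise AlphabetError(f"non-RNA characters in mature sequence {mature!r}")
    if len(mature) < 8:
        raise LengthError("mature sequence shorter than 8 nt; no full seed")
    return mature[1:8]


def canonical_kmers(seed: str, include_6mer: bool = False) -> dict[str, str]:
    """Canonical target-site k-mers for a 7-nt seed, as DNA read 5'->3' on the mRNA.

    * ``7mer-m8``: perfect Watson-Crick match to microRNA positions 2-8
      (= reverse complement of the whole seed).
    * ``7mer-A1``: match to positions 2-7 followed by an adenosine opposite
      microRNA position 1 (the A is recognised directly, not paired).
    * ``8mer``: both, i.e. the 7mer-m8 followed by the A1 adenosine.

    The k-mer's first base pairs the seed's 3'-most base (antiparallel duplex).
    """
    seed = seed.upper()
    if len(seed) != 7:
        raise LengthError(f"seed must be 7 nt, got {len(seed)}")
    if not set(seed) <= RNA_ALPHABET:
        raise AlphabetError(f"non-RNA characters in seed {seed!r}")
    m8 = revcomp_dna(rna_to_dna(seed))
    kmers = {"8mer": m8 + "A", "7mer-m8": m8, "7mer-A1": m8[1:] + "A"}
    if include_6mer:
        kmers[SITE_TYPE_6MER] = m8[1:]
    return kmers


def _normalize_families(families: Iterable) -> dict[str, str]:
    """Map family_id -> seed from an iterable of seeds or MicroRNA objects."""
    out: dict[str, str] = {}
    for fam in families:
        seed = fam.family_id if isinstance(fam, MicroRNA) else str(fam).upper().replace("T", "U")
        out[seed] = seed
    return out


def scan_target_sites(
    utr: UTRRecord,
    families: Iterable,
    site_types: Iterable[str] = SITE_TYPES,
    universe: str = "sense",
) -> list[TargetSite]:
    """Exact canonical-site occurrences of each seed family in a UTR.

    Overlapping occurrences of the *same* family collapse to a single site of
    the strongest type (8mer > 7mer-m8 > 7mer-A1, then leftmost); sites of
    different families are reported independently even when they overlap.
    Windows containing N (or any ambiguity code) never match.
    """
    fams = _normalize_families(families)
    if not fams:
        raise ConfigurationError("empty family list")
    site_types = set(site_types)
    known = set(SITE_TYPES) | {SITE_TYPE_6MER}
    if not site_types or not site_types <= known:
        raise ConfigurationError(f"site_types must be a non-empty subset of {sorted(known)}")

    sites: list[TargetSite] = []
    seq = utr.seq
    for family_id, seed in fams.items():
        kmers = canonical_kmers(seed, include_6mer=SITE_TYPE_6MER in site_types)
        matches: list[tuple[int, int, str]] = []  # (start, end, type), 1-based
        for st in site_types:
            kmer = kmers[st]
            start = seq.find(kmer)
            while start != -1:
                matches.append((start + 1, start + len(kmer), st))
                start = seq.find(kmer, start + 1)
        if not matches:
            continue
        matches.sort(key=lambda m: (m[0], _SITE_RANK.get(m[2], 99)))
        # chain-group overlapping matches of this family, keep strongest/leftmost
        group: list[tuple[int, int, str]] = []
        group_end = -1
        for m in matches:
            if group and m[0] > group_end:
                sites.append(_best_site(utr, family_id, group, universe))
                group = []
            group.append(m)
            group_end = max(group_end, m[1])
        if group:
            sites.append(_best_site(utr, family_id, group, universe))
    sites.sort(key=lambda s: (s.transcript_id, s.start, s.family_id))
    return sites


def _best_site(utr: UTRRecord, family_id: str, group, universe: str) -> TargetSite:
    start, end, st = min(group, key=lambda m: (_SITE_RANK.get(m[2], 99), m[0]))
    return TargetSite(utr.transcript_id, start, end, family_id, st, universe)


def enumerate_near_targets(site_kmer: str) -> set[str]:
    """All k-mers at Hamming distance exactly 1 from a site k-mer (3k of them)."""
    site_kmer = site_kmer.upper()
    if not set(site_kmer) <= DNA_ALPHABET:
        raise AlphabetError(f"non-DNA characters in k-mer {site_kmer!r}")
    out: set[str] = set()
    for i, base in enumerate(site_kmer):
        for alt in "ACGT":
            if alt != base:
                out.add(site_kmer[:i] + alt + site_kmer[i + 1:])
    return out


def _seed_pairing_map(site_kmer: str, seed: str) -> dict[int, int]:
    """Map 1-based k-mer position -> 1-based seed position it pairs with.

    The duplex is antiparallel, so the k-mer's 5' end pairs the seed's 3' end.
    The A1 adenosine of 8mer/7mer-A1 sites is recognised unpaired and maps to
    no seed position.
    """
    kmers = canonical_kmers(seed)
    k = len(site_kmer)
    if k == 8 and site_kmer == kmers["8mer"]:
        return {i: 8 - i for i in range(1, 8)}
    if k == 7 and site_kmer == kmers["7mer-m8"]:
        return {i: 8 - i for i in range(1, 8)}
    if k == 7 and site_kmer == kmers["7mer-A1"]:
        return {i: 7 - i for i in range(1, 7)}
    if k == 6 and site_kmer == kmers["7mer-m8"][1:]:
        return {i: 7 - i for i in range(1, 7)}
    raise ValueError(f"{site_kmer!r} is not a canonical site k-mer for seed {seed!r}")


def is_wobble_near_target(site_kmer: str, variant_kmer: str, seed: str) -> bool:
    """True iff the near-target's single substitution yields a G:U wobble pair.

    At the differing position the variant base is placed opposite the seed base
    it would pair with in the antiparallel duplex; the pair is a wobble when it
    is U:G (variant T opposite seed G) or G:U (variant G opposite seed U).
    Substitutions at the unpaired A1 position can never be wobbles.
    """
    site_kmer, variant_kmer = site_kmer.upper(), variant_kmer.upper()
    if len(site_kmer) != len(variant_kmer):
        raise LengthError("site and variant k-mers differ in length")
    diffs = [i for i, (a, b) in enumerate(zip(site_kmer, variant_kmer)) if a != b]
    if len(diffs) != 1:
        raise ValueError(f"expected Hamming distance 1, got {len(diffs)}")
    pairing = _seed_pairing_map(site_kmer, seed)
    pos = diffs[0] + 1
    seed_pos = pairing.get(pos)
    if seed_pos is None:
        return False
    seed_base = seed.upper()[seed_pos - 1]
    variant_base = variant_kmer[diffs[0]]
    return (variant_base == "T" and seed_base == "G") or (
        variant_base == "G" and seed_base == "U"
    )


def scan_near_targets(
    utr: UTRRecord,
    seed: str,
    site_types: Iterable[str] = ("7mer-m8",),
) -> list[NearTargetWindow]:
    """Windows one substitution away from a family's canonical site k-mers.

    Windows that already are sites of the family are not near-targets and are
    excluded; each returned window records where it differs from the site
    k-mer and whether the difference keeps a G:U wobble pair with the seed.
    """
    seed = seed.upper().replace("T", "U")
    kmers = canonical_kmers(seed, include_6mer=SITE_TYPE_6MER in set(site_types))
    site_kmers = {kmers[st] for st in site_types}
    out: list[NearTargetWindow] = []
    seen: set[tuple[int, str]] = set()
    for st in site_types:
        kmer = kmers[st]
        k = len(kmer)
        near = enumerate_near_targets(kmer)
        for start in range(1, utr.length - k + 2):
            window = utr.seq[start - 1 : start - 1 + k]
            if window in near and window not in site_kmers and (start, window) not in seen:
                seen.add((start, window))
                diff = next(
                    i for i, (a, b) in enumerate(zip(kmer, window), start=1) if a != b
                )
                out.append(
                    NearTargetWindow(
                        transcript_id=utr.transcript_id,
                        start=start,
                        end=start + k - 1,
                        family_id=seed,
                        variant_kmer=window,
                        diff_pos=diff,
                        wobble=is_wobble_near_target(kmer, window, seed),
                    )
                )
    out.sort(key=lambda w: (w.start, w.end))
    return out


def rc_background(utr: UTRRecord, snps: Sequence = ()) -> tuple[UTRRecord, list]:
    """Reverse-complement universe of a UTR and its SNPs.

    Scanning this universe for target sites yields a background with identical
    length and base composition but no biological targeting, the null used for
    the allele-frequency comparisons.  SNP positions map to ``L - pos + 1`` and
    alleles are complemented; frequencies and ancestral labels are untouched.
    Applying the transform twice returns the original records.
    """
    rc_utr = UTRRecord(utr.transcript_id, utr.gene_id, revcomp_dna(utr.seq))
    L = utr.length
    rc_snps = []
    for snp in snps:
        if not 1 <= snp.pos <= L:
            raise ValueError(f"SNP {snp.snp_id!r} position {snp.pos} outside UTR of length {L}")
        rc_snps.append(
            dataclasses.replace(
                snp,
                pos=L - snp.pos + 1,
                ref_allele=snp.ref_allele.translate(_DNA_COMPLEMENT),
                alt_allele=snp.alt_allele.translate(_DNA_COMPLEMENT),
            )
        )
    return rc_utr, rc_snps
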