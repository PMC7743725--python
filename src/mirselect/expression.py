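"""MicroRNA expression summaries, coexpression and APA filters.

Selective pressure on a target site only exists where the microRNA and its
host transcript are actually coexpressed, so the allele-frequency analyses are
run per tissue on pairs whose microRNA family is expressed there and whose
transcript is detected there.  MicroRNA abundance is summarised as mean reads
per million (RPM) across expression experiments and discretised into four
classes: none (0), low (<=50), moderate (>50) and high (>500).  Families whose
every member is undetected in all experiments for a tissue provide the
zero-expression background; 3'-UTRs with tissue-specific polyadenylation
evidence (APA) can additionally be required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, InsufficientDataError
from .seqsites import MicroRNA

EXPRESSION_CLASSES = ("none", "low", "moderate", "high")
_CLASS_RANK = {c: i for i, c in enumerate(EXPRESSION_CLASSES)}

#: mean-RPM thresholds: strictly more than 50 is moderate, more than 500 high
MODERATE_RPM = 50.0
HIGH_RPM = 500.0

EXPRESSION_COLUMNS = ("mirna", "tissue", "experiment", "rpm")


@dataclass
class TissueContext:
    """Which transcripts are detected (and optionally polyadenylated) in a tissue."""

    tissue: str
    expressed_transcripts: set = field(default_factory=set)
    apa_transcripts: set | None = None


def validate_expression_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (mirna, tissue, experiment, rpm) long-format expression table."""
    missing = set(EXPRESSION_COLUMNS) - set(table.columns)
    if missing:
        raise ConfigurationError(f"expression table missing columns: {sorted(missing)}")
    if (table["rpm"] < 0).any():
        raise ValueError("negative RPM in expression table")
    if table.duplicated(subset=["mirna", "tissue", "experiment"]).any():
        raise ValueError("duplicate (mirna, tissue, experiment) rows in expression table")
    return table


def mean_rpm(table: pd.DataFrame, mirna: str, tissue: str) -> float:
    """Arithmetic mean RPM of one microRNA across a tissue's experiments."""
    rows = table[(table["mirna"] == mirna) & (table["tissue"] == tissue)]
    if rows.empty:
        raise LookupError(f"no expression rows for {mirna!r} in {tissue!r}")
    return float(rows["rpm"].mean())


def expression_class(value: float) -> str:
    """Discretise a mean RPM: 0 -> none, (0,50] -> low, (50,500] -> moderate, >500 -> high."""
    if value < 0:
        raise ValueError(f"negative mean RPM: {value}")
    if value == 0:
        return "none"
    if value <= MODERATE_RPM:
        return "low"
    if value <= HIGH_RPM:
        return "moderate"
    return "high"


def class_at_least(cls: str, min_class: str) -> bool:
    return _CLASS_RANK[cls] >= _CLASS_RANK[min_class]


def annotate_expression(mirnas: Sequence[MicroRNA], table: pd.DataFrame) -> None:
    """Fill each microRNA's ``expression`` map (tissue -> mean RPM) from the table."""
    means = table.groupby(["mirna", "tissue"])["rpm"].mean()
    for m in mirnas:
        m.expression = {
            tissue: float(v) for (name, tissue), v in means.items() if name == m.name
        }


def family_members(mirnas: Sequence[MicroRNA], family_id: str) -> list[MicroRNA]:
    return [m for m in mirnas if m.family_id == family_id]


def family_expression_class(mirnas: Sequence[MicroRNA], family_id: str, tissue: str) -> str:
    """Expression class of a seed family = the maximum class over its members.

    A site is avoided if any member microRNA carrying the seed is present, so
    the family is as expressed as its most expressed member.
    """
    members = family_members(mirnas, family_id)
    if not members:
        raise LookupError(f"no microRNA with family {family_id!r}")
    best = "none"
    for m in members:
        cls = expression_class(m.expression.get(tissue, 0.0))
        if _CLASS_RANK[cls] > _CLASS_RANK[best]:
            best = cls
    return best


def coexpressed_pairs(
    pairs: Sequence,
    mirnas: Sequence[MicroRNA],
    tissue_context: TissueContext,
    min_class: str = "moderate",
) -> list:
    """Pairs whose family is expressed (>= min_class) and transcript detected in the tissue."""
    if min_class not in ("moderate", "high"):
        raise ConfigurationError(f"min_class must be 'moderate' or 'high', got {min_class!r}")
    tissue = tissue_context.tissue
    if not any(tissue in m.expression for m in mirnas):
        raise InsufficientDataError(f"no expression data loaded for tissue {tissue!r}")
    kept = []
    for p in pairs:
        if p.transcript_id not in tissue_context.expressed_transcripts:
            continue
        if class_at_least(family_expression_class(mirnas, p.family_id, tissue), min_class):
            kept.append(p)
    return kept


def apa_filter(pairs: Sequence, tissue_context: TissueContext) -> list:
    """Keep pairs whose 3'-UTR has polyadenylation evidence in the tissue."""
    if tissue_context.apa_transcripts is None:
        raise InsufficientDataError(
            f"no APA data for tissue {tissue_context.tissue!r}; skip the APA filter"
        )
    return [p for p in pairs if p.transcript_id in tissue_context.apa_transcripts]


def null_mirna_background(
    pairs: Sequence,
    mirnas: Sequence[MicroRNA],
    tissue: str,
    table: pd.DataFrame | None = None,
) -> list:
    """Pairs of families with no detectable expression, the zero-expression null.

    A family belongs to the background only when *every* member microRNA has
    zero reads.  When the raw experiment table is given, zero is required in
    every experiment for the tissue, not merely a zero mean.
    """
    def member_silent(m: MicroRNA) -> bool:
        if table is not None:
            rows = table[(table["mirna"] == m.name) & (table["tissue"] == tissue)]
            if not rows.empty:
                return bool((rows["rpm"] == 0).all())
        return m.expression.get(tissue, 0.0) == 0.0

    silent_families = set()
    seen_families = set()
    for m in mirnas:
        seen_families.add(m.family_id)
    for fam in seen_families:
        if all(member_silent(m) for m in family_members(mirnas, fam)):
            silent_families.add(fam)
    return [p for p in pairs if p.family_id in silent_families]
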