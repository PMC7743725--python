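"""End-to-end analyses: overlay, DAF shift tests, rank model, Fst, seed shifts.

Each function takes in-memory objects (UTRs, microRNAs, SNPs, expression
table, tissue contexts) and produces tidy tables, so runs are scriptable from
Python; the command-line layer in :mod:`mirselect.cli` is a thin wrapper over
these functions plus the file readers in :mod:`mirselect.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, NoInformationError
from .expression import (
    TissueContext,
    apa_filter,
    coexpressed_pairs,
    family_expression_class,
    family_members,
    null_mirna_background,
)
from .overlay import (
    AlleleTargetPair,
    SNP,
    high_fst_table,
    maf_filter,
    overlay_snps,
    pairs_to_frame,
    polarize,
)
from .popstats import (
    SRHResult,
    bh_qvalues,
    expected_fp_mask,
    fst_enrichment,
    ks_one_tailed,
    srh_test,
    wilcoxon_paired,
)
from .seqsites import SITE_TYPES, MicroRNA, UTRRecord, rc_background

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis settings shared by the pipeline commands."""

    tissues: tuple = ()
    site_types: tuple = SITE_TYPES
    min_class: str = "high"
    background_kind: str = "revcomp"
    maf_threshold: float = 0.01
    fdr_ceiling: float = 0.10
    fst_cutoff: float = 0.6
    fst_bin_width: float = 0.05
    fst_log_base: float = 10.0
    rng_seed: int = 0


def build_pairs(
    utrs: Sequence[UTRRecord],
    mirnas: Sequence[MicroRNA],
    snps: Sequence[SNP],
    site_types: Iterable[str] = SITE_TYPES,
    maf_threshold: float | None = 0.01,
) -> tuple[list[AlleleTargetPair], list[AlleleTargetPair]]:
    """Overlay SNPs on both universes and polarize.

    Returns (sense pairs, reverse-complement background pairs), each polarized
    and MAF-filtered (pass ``maf_threshold=None`` to skip the filter).
    """
    by_transcript: dict[str, list[SNP]] = {}
    for s in snps:
        by_transcript.setdefault(s.transcript_id, []).append(s)
    families = sorted({m.family_id for m in mirnas})
    sense: list[AlleleTargetPair] = []
    background: list[AlleleTargetPair] = []
    for utr in utrs:
        here = by_transcript.get(utr.transcript_id, [])
        if not here:
            continue
        snp_by_id = {s.snp_id: s for s in here}
        for pair in overlay_snps(utr, families, here, site_types):
            sense.append(polarize(pair, snp_by_id[pair.snp_id]))
        rc_utr, rc_snps = rc_background(utr, here)
        rc_by_id = {s.snp_id: s for s in rc_snps}
        for pair in overlay_snps(rc_utr, families, rc_snps, site_types,
                                 universe="revcomp-background"):
            background.append(polarize(pair, rc_by_id[pair.snp_id]))
    if maf_threshold is not None:
        sense = maf_filter(sense, maf_threshold)
        background = maf_filter(background, maf_threshold)
    logger.info("overlay: %d sense pairs, %d background pairs", len(sense), len(background))
    return sense, background


def _dafs(pairs: Sequence[AlleleTargetPair], polarity: str) -> np.ndarray:
    return np.array([p.daf for p in pairs if p.polarity == polarity and p.daf is not None])


def daf_analysis(
    sense_pairs: Sequence[AlleleTargetPair],
    background_pairs: Sequence[AlleleTargetPair],
    mirnas: Sequence[MicroRNA],
    tissue_contexts: Mapping[str, TissueContext],
    tissues: Sequence[str],
    expression_table: pd.DataFrame | None = None,
    background_kind: str = "revcomp",
    min_class: str = "high",
    polarity: str = "target-derived",
    fdr_ceiling: float = 0.10,
    wobble_partition: bool = False,
    apa: bool = False,
) -> pd.DataFrame:
    """Per-tissue one-tailed KS comparison of DAF distributions.

    For each tissue, the target sample is the DAFs of coexpressed pairs with
    the requested polarity, and the background is either the same analysis on
    the reverse-complement universe (``background_kind='revcomp'``) or the
    sense-strand pairs of families with no detectable expression
    (``'null-mirna'``).  The shift is tested toward the ancestral allele (low
    DAF); q-values control the FDR across the tissue family of tests and the
    discovery flag additionally requires <1 expected false positive.  With
    ``wobble_partition=True`` each tissue contributes separate rows for pairs
    whose near-target allele keeps a G:U wobble and for those that do not.
    """
    rows = []
    for tissue in tissues:
        ctx = tissue_contexts[tissue]
        try:
            targets = coexpressed_pairs(sense_pairs, mirnas, ctx, min_class)
            if background_kind == "revcomp":
                bg = coexpressed_pairs(background_pairs, mirnas, ctx, min_class)
            elif background_kind == "null-mirna":
                bg = null_mirna_background(sense_pairs, mirnas, tissue, expression_table)
            else:
                raise ValueError(f"unknown background_kind {background_kind!r}")
            if apa:
                targets = apa_filter(targets, ctx)
                bg = apa_filter(bg, ctx)
        except InsufficientDataError as exc:
            rows.append(_failed_row(tissue, background_kind, polarity, str(exc)))
            continue
        subsets = (
            [("all", targets)] if not wobble_partition
            else [("wobble", [p for p in targets if p.wobble]),
                  ("non-wobble", [p for p in targets if not p.wobble])]
        )
        for label, subset in subsets:
            t = _dafs(subset, polarity)
            b = _dafs(bg, polarity)
            if t.size == 0 or b.size == 0:
                row = _failed_row(tissue, background_kind, polarity, "insufficient data")
                row["subset"] = label
                rows.append(row)
                continue
            d, p = ks_one_tailed(t, b, direction="toward-ancestral")
            rows.append({
                "tissue": tissue, "subset": label, "background_kind": background_kind,
                "polarity_tested": polarity, "n_target": t.size, "n_background": b.size,
                "D_signed": d, "p_value": p, "status": "ok",
            })
    frame = pd.DataFrame(rows)
    ok = frame["status"] == "ok"
    frame["q_value"] = np.nan
    frame["discovery"] = False
    if ok.any():
        q = bh_qvalues(frame.loc[ok, "p_value"].values)
        frame.loc[ok, "q_value"] = q
        frame.loc[ok, "discovery"] = expected_fp_mask(q, fdr_ceiling)
    return frame


def daf_frame_to_results(frame: pd.DataFrame):
    """Typed view of the successful rows of a :func:`daf_analysis` table."""
    from .popstats import DAFTestResult

    out = []
    for row in frame.itertuples(index=False):
        if row.status != "ok":
            continue
        out.append(DAFTestResult(
            tissue=row.tissue, background_kind=row.background_kind,
            polarity_tested=row.polarity_tested, n_target=int(row.n_target),
            n_background=int(row.n_background), D_signed=float(row.D_signed),
            p_value=float(row.p_value), q_value=float(row.q_value),
        ))
    return out


def _failed_row(tissue, background_kind, polarity, message):
    return {
        "tissue": tissue, "subset": "all", "background_kind": background_kind,
        "polarity_tested": polarity, "n_target": 0, "n_background": 0,
        "D_signed": np.nan, "p_value": np.nan, "status": message,
    }


def srh_analysis(
    sense_pairs: Sequence[AlleleTargetPair],
    mirnas: Sequence[MicroRNA],
    tissues: Sequence[str],
    polarity: str = "target-derived",
    reference: tuple = ("high", "animal"),
) -> dict[str, SRHResult]:
    """Joint effect of family expression and conservation on DAF ranks.

    For each tissue, pairs with the requested polarity are annotated with
    their family's expression class in that tissue (none-class families are
    excluded) and the family's conservation class, and the ranked two-way
    model with interaction is fitted; the intercept is the (high expression,
    animal conservation) cell, so coefficients are rank shifts relative to the
    cell expected to be under the strongest selection.
    """
    cons_by_family: dict[str, str] = {}
    for m in mirnas:
        best = cons_by_family.get(m.family_id)
        order = {"primate": 0, "mammal": 1, "animal": 2, "unknown": -1}
        if best is None or order[m.conservation] > order[best]:
            cons_by_family[m.family_id] = m.conservation
    results: dict[str, SRHResult] = {}
    for tissue in tissues:
        y, fa, fb = [], [], []
        for p in sense_pairs:
            if p.polarity != polarity or p.daf is None:
                continue
            cls = family_expression_class(mirnas, p.family_id, tissue)
            if cls == "none":
                continue
            y.append(p.daf)
            fa.append(cls)
            fb.append(cons_by_family.get(p.family_id, "unknown"))
        ref = reference if (reference[0] in fa and reference[1] in fb) else None
        results[tissue] = srh_test(y, fa, fb, reference=ref)
    return results


def fst_analysis(
    sense_pairs: Sequence[AlleleTargetPair],
    background_pairs: Sequence[AlleleTargetPair],
    mirnas: Sequence[MicroRNA],
    fst: Mapping[str, float] | pd.Series,
    tissue: str,
    expression_classes: Sequence[str] = ("high",),
    bin_width: float = 0.05,
    log_base: float = 10.0,
    cutoff: float = 0.6,
) -> dict:
    """Fst-bin enrichment of target-site SNPs over the background universe.

    For each requested family expression class, enrichment curves log(Pt/Pb)
    are computed for all pairs of that class and separately for the
    target-ancestral and target-derived partitions; SNPs without an Fst value
    are skipped.  Also returns the high-Fst table at ``cutoff``.
    """
    fst = pd.Series(dict(fst)) if not isinstance(fst, pd.Series) else fst

    def fsts(pairs):
        vals = [fst[p.snp_id] for p in pairs if p.snp_id in fst.index]
        return np.array(vals)

    bg = fsts(background_pairs)
    out: dict = {"curves": {}, "counts": {}}
    for cls in expression_classes:
        of_class = [
            p for p in sense_pairs
            if family_expression_class(mirnas, p.family_id, tissue) == cls
        ]
        partitions = {
            "all": of_class,
            "target-ancestral": [p for p in of_class if p.polarity == "target-ancestral"],
            "target-derived": [p for p in of_class if p.polarity == "target-derived"],
        }
        for name, subset in partitions.items():
            t = fsts(subset)
            key = (cls, name)
            out["counts"][key] = (t.size, bg.size)
            if t.size == 0 or bg.size == 0:
                out["curves"][key] = None
            else:
                out["curves"][key] = fst_enrichment(t, bg, bin_width, log_base)
    table, counts = high_fst_table(list(sense_pairs), fst, cutoff)
    out["high_fst_table"] = table
    out["high_fst_counts"] = counts
    return out


def seedshift_analysis(
    sense_pairs: Sequence[AlleleTargetPair],
    family_id: str,
    pop_a: str = "EUR",
    pop_b: str = "AFR",
    polarity: str = "target-ancestral",
) -> tuple[pd.DataFrame, float]:
    """Paired population comparison of target-allele frequencies for one family.

    Collects the sites targeted by the given seed family with the requested
    polarity (by default ancestral targets, the sites relevant when a derived
    seed variant of the microRNA spreads through a population) and compares
    the per-site target-allele frequency between two populations with a
    paired Wilcoxon signed-rank test.  Returns the per-site table and the
    two-sided p-value.
    """
    rows = []
    for p in sense_pairs:
        if p.family_id != family_id or p.polarity != polarity:
            continue
        if pop_a not in p.target_allele_freq or pop_b not in p.target_allele_freq:
            raise InsufficientDataError(
                f"populations {pop_a!r}/{pop_b!r} absent from frequency table"
            )
        rows.append({"snp_id": p.snp_id, "transcript_id": p.transcript_id,
                     pop_a: p.target_allele_freq[pop_a], pop_b: p.target_allele_freq[pop_b]})
    if not rows:
        raise InsufficientDataError(f"no {polarity} pairs for family {family_id!r}")
    frame = pd.DataFrame(rows)
    p_value = wilcoxon_paired(frame[pop_a].values, frame[pop_b].values)
    return frame, p_value


def srh_results_to_frame(results: Mapping[str, SRHResult]) -> pd.DataFrame:
    rows = []
    for tissue, res in results.items():
        for effect in res.H:
            rows.append({
                "tissue": tissue, "effect": effect, "H": res.H[effect],
                "df": res.df[effect], "p_value": res.p[effect],
            })
    return pd.DataFrame(rows)


def enrichment_to_frame(curves: Mapping) -> pd.DataFrame:
    rows = []
    for (cls, partition), bins in curves.items():
        if bins is None:
            continue
        for b in bins:
            rows.append({
                "expression_class": cls, "partition": partition,
                "fst_lo": b.fst_lo, "fst_hi": b.fst_hi, "P_t": b.P_t, "P_b": b.P_b,
                "log_ratio": b.log_ratio, "defined": b.defined,
            })
    return pd.DataFrame(rows)
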