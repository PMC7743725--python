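"""Readers and writers for the flat-file dialects the pipeline speaks.

FASTA for UTRs (headers ``transcript_id|gene_id``) and mature microRNAs
(headers carry the name), TSV for SNPs, expression tables, conservation
classes, tissue contexts, per-SNP Fst and population latitudes, and plain-text
VCF for SNPs via pysam with a BED-style table mapping UTRs to genomic
intervals.  A small packaged catalog of high-Fst target-site SNPs across the
1000 Genomes superpopulations ships with the package for the reanalysis
example.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError
from .expression import TissueContext, validate_expression_table
from .overlay import SNP, AlleleTargetPair, pairs_to_frame
from .seqsites import MicroRNA, UTRRecord

SNP_COLUMNS = ("snp_id", "transcript_id", "pos", "ref_allele", "alt_allele",
               "ancestral", "global_freq")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_utr_fasta(path) -> list[UTRRecord]:
    """UTRs from FASTA; headers are ``transcript_id|gene_id``."""
    utrs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        tid = parts[0]
        gid = parts[1] if len(parts) > 1 else tid
        utrs.append(UTRRecord(tid, gid, str(rec.seq)))
    return utrs


def write_utr_fasta(utrs: Sequence[UTRRecord], path) -> None:
    records = [
        SeqRecord(Seq(u.seq), id=f"{u.transcript_id}|{u.gene_id}", description="")
        for u in utrs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_mirna_fasta(path) -> list[MicroRNA]:
    """Mature microRNAs from FASTA (RNA alphabet); header is the name."""
    return [MicroRNA(name=rec.id, mature=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_mirna_fasta(mirnas: Sequence[MicroRNA], path) -> None:
    records = [SeqRecord(Seq(m.mature), id=m.name, description="") for m in mirnas]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

def read_snps_tsv(path) -> list[SNP]:
    """SNPs from a flat TSV; per-population alt-frequency columns are ``freq_POP``."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SNP_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigurationError(f"SNP table missing columns: {sorted(missing)}")
    pop_cols = [c for c in frame.columns if c.startswith("freq_")]
    snps = []
    for row in frame.itertuples(index=False):
        freq = {c[len("freq_"):]: float(getattr(row, c)) for c in pop_cols}
        snps.append(
            SNP(
                snp_id=str(row.snp_id), transcript_id=str(row.transcript_id),
                pos=int(row.pos), ref_allele=str(row.ref_allele),
                alt_allele=str(row.alt_allele), ancestral=str(row.ancestral),
                freq=freq, global_freq=float(row.global_freq),
            )
        )
    return snps


def write_snps_tsv(snps: Sequence[SNP], path) -> None:
    pops: list[str] = []
    for s in snps:
        for pop in s.freq:
            if pop not in pops:
                pops.append(pop)
    rows = []
    for s in snps:
        row = {
            "snp_id": s.snp_id, "transcript_id": s.transcript_id, "pos": s.pos,
            "ref_allele": s.ref_allele, "alt_allele": s.alt_allele,
            "ancestral": s.ancestral, "global_freq": s.global_freq,
        }
        for pop in pops:
            row[f"freq_{pop}"] = s.freq.get(pop, float("nan"))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_utr_coordinates(path) -> pd.DataFrame:
    """BED-style UTR coordinate table: transcript_id, chrom, start, end, strand.

    ``start``/``end`` are 1-based inclusive genomic coordinates of the UTR.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    needed = {"transcript_id", "chrom", "start", "end", "strand"}
    missing = needed - set(frame.columns)
    if missing:
        raise ConfigurationError(f"coordinate table missing columns: {sorted(missing)}")
    return frame


def read_snps_vcf(path, coords: pd.DataFrame) -> list[SNP]:
    """Biallelic SNPs from a VCF mapped into UTR coordinates.

    Uses INFO/AA for the ancestral allele and INFO/AF (plus any
    ``<POP>_AF`` tags) for frequencies.  Multiallelic or non-SNP records are
    skipped.  Minus-strand UTRs get complemented alleles and flipped
    coordinates so that positions always run 5'->3' along the UTR.
    """
    import pysam

    comp = str.maketrans("ACGT", "TGCA")
    snps: list[SNP] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            hits = coords[
                (coords["chrom"] == rec.chrom)
                & (coords["start"] <= rec.pos)
                & (coords["end"] >= rec.pos)
            ]
            for utr in hits.itertuples(index=False):
                if utr.strand == "+":
                    pos = rec.pos - utr.start + 1
                    r, a = ref, alt
                else:
                    pos = utr.end - rec.pos + 1
                    r, a = ref.translate(comp), alt.translate(comp)
                aa = rec.info.get("AA")
                if isinstance(aa, tuple):
                    aa = aa[0]
                aa = (aa or "").split("|")[0].upper()
                if utr.strand == "-" and aa in "ACGT":
                    aa = aa.translate(comp)
                if aa == r:
                    ancestral = "ref"
                elif aa == a:
                    ancestral = "alt"
                else:
                    ancestral = "unknown"
                af = rec.info.get("AF")
                gf = float(af[0] if isinstance(af, tuple) else af) if af is not None else float("nan")
                freq = {}
                for key in rec.info.keys():
                    if key.endswith("_AF"):
                        v = rec.info.get(key)
                        freq[key[:-3]] = float(v[0] if isinstance(v, tuple) else v)
                snps.append(
                    SNP(snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                        transcript_id=utr.transcript_id, pos=int(pos),
                        ref_allele=r, alt_allele=a, ancestral=ancestral,
                        freq=freq, global_freq=gf)
                )
    return snps


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def read_expression_tsv(path) -> pd.DataFrame:
    return validate_expression_table(pd.read_csv(path, sep="\t", comment="#"))


def read_conservation_tsv(path) -> dict[str, str]:
    """Map microRNA name -> conservation class from a two-column TSV."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(frame["mirna"].astype(str), frame["conservation"].astype(str)))


def apply_conservation(mirnas: Sequence[MicroRNA], classes: Mapping[str, str]) -> None:
    for m in mirnas:
        if m.name in classes:
            m.conservation = classes[m.name]


def read_fst_tsv(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", comment="#")
    fst = pd.Series(frame["fst"].astype(float).values, index=frame["snp_id"].astype(str))
    if ((fst < 0) | (fst > 1)).any():
        raise ValueError("Fst values outside [0,1]")
    return fst


def read_latitudes_tsv(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return pd.Series(frame["abs_latitude"].astype(float).values,
                     index=frame["population"].astype(str))


def read_tissue_context_tsv(path, tissue: str) -> TissueContext:
    """Tissue context from a long TSV: tissue, transcript_id, kind(expressed|apa)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    rows = frame[frame["tissue"] == tissue]
    expressed = set(rows.loc[rows["kind"] == "expressed", "transcript_id"].astype(str))
    apa_rows = rows[rows["kind"] == "apa"]
    apa = set(apa_rows["transcript_id"].astype(str)) if not apa_rows.empty else None
    return TissueContext(tissue=tissue, expressed_transcripts=expressed, apa_transcripts=apa)


def write_tissue_contexts_tsv(contexts: Mapping[str, TissueContext], path) -> None:
    rows = []
    for tissue, ctx in contexts.items():
        for tid in sorted(ctx.expressed_transcripts):
            rows.append({"tissue": tissue, "transcript_id": tid, "kind": "expressed"})
        for tid in sorted(ctx.apa_transcripts or ()):
            rows.append({"tissue": tissue, "transcript_id": tid, "kind": "apa"})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# universe round-trip
# ---------------------------------------------------------------------------

def write_universe(universe, outdir) -> dict:
    """Write a simulated universe to a directory; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_utr_fasta(universe.utrs, out / "utrs.fa")
    write_mirna_fasta(universe.mirnas, out / "mirnas.fa")
    write_snps_tsv(universe.snps, out / "snps.tsv")
    universe.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"mirna": [m.name for m in universe.mirnas],
         "conservation": [m.conservation for m in universe.mirnas]}
    ).to_csv(out / "conservation.tsv", sep="\t", index=False)
    write_tissue_contexts_tsv(universe.tissue_contexts, out / "tissue_context.tsv")
    universe.truth.to_csv(out / "truth_table.tsv", sep="\t", index=False)
    manifest = {
        "rng_seed": universe.config.rng_seed,
        "outputs": ["utrs.fa", "mirnas.fa", "snps.tsv", "expression.tsv",
                    "conservation.tsv", "tissue_context.tsv", "truth_table.tsv"],
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(universe.config).items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def sites_to_frame(sites) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"transcript_id": s.transcript_id, "start": s.start, "end": s.end,
             "family_id": s.family_id, "site_type": s.site_type, "universe": s.universe}
            for s in sites
        ]
    )


# ---------------------------------------------------------------------------
# packaged catalog
# ---------------------------------------------------------------------------

def load_high_fst_catalog() -> tuple[pd.DataFrame, pd.Series]:
    """Catalog of target-site SNPs with high population differentiation.

    Returns a pair (pairs-frame, Fst series).  The frame carries one row per
    SNP with the representative microRNA of the targeting family, the host
    gene, the polarity of the target allele and its frequency in the five
    1000 Genomes superpopulations plus the pooled sample; the series maps
    snp_id -> Fst.
    """
    path = resources.files("mirselect") / "data" / "high_fst_catalog.tsv"
    frame = pd.read_csv(path, sep="\t", comment="#")
    polarity = frame["target_state"].map(
        {"a": "target-ancestral", "d": "target-derived"}
    )
    pairs = frame.assign(polarity=polarity).drop(columns=["target_state"])
    fst = pd.Series(frame["fst"].values, index=frame["snp_id"])
    return pairs.drop(columns=["fst"]), fst
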