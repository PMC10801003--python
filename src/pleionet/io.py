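"""Readers and writers for the pipeline's file formats.

Conventions: all coordinates are 1-based inclusive inside the package;
BED input (0-based half-open) is converted on read. The internal
interchange format for genotypes is a dosage TSV (samples x markers) with
a marker-map sidecar; VCF is supported at the boundary. Output tables
written by pipeline stages carry '#' header lines naming the producing
stage and the configuration hash, which pandas skips on read via
``comment='#'``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GeneModel, GenotypeMatrix, QTLRegion, validate_phenotypes

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- genotypes

def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic records from a VCF 4.x with GT fields as alt dosages.

    Multi-allelic records are skipped (count logged); missing genotypes
    become the missing code. Positions stay 1-based as in VCF.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on bad headers
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, dosages = [], []
    n_multi = 0
    for line_no, rec in enumerate(vcf, 1):
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = np.asarray(rec.genotype.array())[:, :2]
        dos = np.where((gts < 0).any(axis=1), MISSING, gts.clip(min=0).sum(axis=1))
        if rec.POS <= 0:
            raise ValueError(f"malformed VCF record at data line {line_no}: POS={rec.POS}")
        rows.append({
            "chrom": rec.CHROM, "pos": rec.POS,
            "id": rec.ID or f"{rec.CHROM}_{rec.POS}",
            "ref": rec.REF, "alt": rec.ALT[0],
        })
        dosages.append(dos.astype(np.int8))
    if n_multi:
        logger.info("read_vcf(%s): skipped %d multi-allelic records", path, n_multi)
    if not rows:
        raise ValueError(f"no biallelic records in VCF {path}")
    markers = pd.DataFrame(rows)
    return GenotypeMatrix(dosage=np.array(dosages).T, markers=markers, samples=samples)


_GT_OF_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (unphased GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pleionet\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(geno.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        for j, mk in geno.markers.iterrows():
            gts = "\t".join(_GT_OF_DOSAGE[int(d)] for d in geno.dosage[:, j])
            fh.write(f"{mk['chrom']}\t{mk['pos']}\t{mk['id']}\t{mk['ref']}\t{mk['alt']}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def write_dosage_tsv(geno: GenotypeMatrix, prefix) -> tuple[str, str]:
    """Write dosage matrix + marker-map sidecar; returns the two paths."""
    prefix = Path(prefix)
    dosage_path = prefix.with_suffix(".dosage.tsv")
    map_path = prefix.with_suffix(".markers.tsv")
    df = pd.DataFrame(geno.dosage, index=pd.Index(geno.samples, name="sample"),
                      columns=geno.markers["id"])
    df.to_csv(dosage_path, sep="\t")
    geno.markers.to_csv(map_path, sep="\t", index=False)
    return str(dosage_path), str(map_path)


def read_dosage_tsv(dosage_path, map_path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col=0, comment="#")
    markers = pd.read_csv(map_path, sep="\t", comment="#")
    if list(df.columns) != list(markers["id"].astype(str)):
        raise ValueError("dosage columns do not match the marker map order")
    return GenotypeMatrix(
        dosage=df.to_numpy(np.int8),
        markers=markers,
        samples=[str(s) for s in df.index],
    )


# --------------------------------------------------------------- phenotypes

def write_phenotypes(pheno: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    validate_phenotypes(pheno)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pheno.to_csv(fh, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str, "env": str})
    return validate_phenotypes(pheno)


# ---------------------------------------------------------------- intervals

def read_bed_intervals(path) -> pd.DataFrame:
    """Read a 3+ column BED into 1-based inclusive (chrom, start, end, name).

    BED is 0-based half-open: internal start = bed_start + 1, end = bed_end.
    Records with start >= end are rejected and logged.
    """
    rows = []
    with open(path) as fh:
        for k, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {k}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                logger.warning("BED line %d rejected: start %d >= end %d", k, start, end)
                continue
            rows.append({
                "chrom": chrom, "start": start + 1, "end": end,
                "name": parts[3] if len(parts) > 3 else f"interval_{k}",
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed_intervals(intervals: pd.DataFrame, path) -> None:
    """Write 1-based inclusive intervals back out as BED (inverse of read)."""
    with open(path, "w") as fh:
        for _, r in intervals.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t{r['name']}\n")


def read_catalog(path) -> pd.DataFrame:
    """Known-QTL catalog: BED or TSV with 1-based inclusive chrom/start/end/name."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return read_bed_intervals(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"chrom", "start", "end", "name"}
    if not needed.issubset(df.columns):
        raise ValueError(f"catalog TSV must have columns {sorted(needed)}")
    return df[["chrom", "start", "end", "name"]]


# -------------------------------------------------------------- gene models

def read_gff3_genes(path) -> list[GeneModel]:
    """Gene models (feature type 'gene') from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gene_id=gene_id, chrom=feat.seqid,
                               start=feat.start, end=feat.end, strand=feat.strand))
    return genes


# ------------------------------------------------------------------- tables

def qtl_table(qtls: list[QTLRegion]) -> pd.DataFrame:
    """QTL regions as a table mirroring the standard report columns."""
    return pd.DataFrame([{
        "id": q.id, "trait": q.trait, "minus_log10_p": -np.log10(q.min_p),
        "chrom": q.chrom, "start": q.start, "end": q.end,
        "environments": ",".join(q.environments),
        "index_marker": q.index_marker, "n_members": len(q.member_markers),
    } for q in qtls])


def write_table(df: pd.DataFrame, path, stage: str, config_hash: str = "") -> None:
    """Write a TSV with a '#' header naming the producing stage."""
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n")
        if config_hash:
            fh.write(f"# config: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


__all__ = [
    "read_vcf", "write_vcf",
    "write_dosage_tsv", "read_dosage_tsv",
    "write_phenotypes", "read_phenotypes",
    "read_bed_intervals", "write_bed_intervals", "read_catalog",
    "read_gff3_genes",
    "qtl_table", "write_table",
]
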