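"""Readers and writers for the pipeline's on-disk formats.

Conventions: coordinates are 1-based inclusive internally; BED I/O converts
to/from 0-based half-open.  TSVs are tab-separated, UTF-8, unquoted, with
'#'-prefixed header/provenance lines.  Chromosome names are normalised by
stripping an optional "chr" prefix.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "normalize_chrom",
    "provenance_header",
    "read_tsv",
    "write_tsv",
    "read_variant_sites_tsv",
    "write_variant_sites_tsv",
    "write_pooled_vcf",
    "read_pooled_vcf",
    "read_parental_vcf",
    "read_gene_annotation",
    "write_gene_bed",
    "read_counts",
    "write_counts",
    "read_design",
    "read_chrom_lengths",
    "read_de_results",
    "write_de_results",
    "read_go_annotation",
]

POOL_TSV_COLUMNS = ["chrom", "pos", "ref_mut", "alt_mut", "ref_sib", "alt_sib", "qual"]


def normalize_chrom(name) -> str:
    name = str(name)
    return name[3:] if name.lower().startswith("chr") else name


def provenance_header(stage: str, seed=None, config: dict | None = None) -> str:
    """One '#'-comment line recording tool version, config hash and seed."""
    from . import __version__

    digest = ""
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
    parts = [f"#asemap v{__version__}", f"stage={stage}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if digest:
        parts.append(f"config={digest}")
    return " ".join(parts)


def write_tsv(frame: pd.DataFrame, path, stage: str = "", seed=None, config=None, index=False):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if stage:
            fh.write(provenance_header(stage, seed, config) + "\n")
        frame.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# pooled variant sites


def write_variant_sites_tsv(sites: pd.DataFrame, path, **meta):
    write_tsv(sites[POOL_TSV_COLUMNS], path, stage="pool-sites", **meta)


def read_variant_sites_tsv(path) -> pd.DataFrame:
    frame = read_tsv(path, dtype={"chrom": str})
    missing = set(POOL_TSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"pooled-sites TSV missing columns: {sorted(missing)}")
    frame["chrom"] = frame["chrom"].map(normalize_chrom)
    return frame


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=asemap
##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tmutant\tsibling
"""


def write_pooled_vcf(sites: pd.DataFrame, path, chrom_lengths: dict | None = None):
    """Two-sample VCF v4.2 (mutant, sibling) with AD per pool and site QUAL.

    Ref/alt bases are placeholders (A/T): the pipeline consumes depths, not
    sequence.
    """
    contigs = ""
    if chrom_lengths:
        contigs = "".join(
            f"##contig=<ID={c},length={int(l)}>\n" for c, l in chrom_lengths.items()
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs))
        for r in sites.itertuples():
            fh.write(
                f"{r.chrom}\t{int(r.pos)}\t.\tA\tT\t{r.qual:g}\t.\tNS=2\tAD\t"
                f"{int(r.ref_mut)},{int(r.alt_mut)}\t{int(r.ref_sib)},{int(r.alt_sib)}\n"
            )


def read_pooled_vcf(path) -> pd.DataFrame:
    """Read a two-sample pooled VCF into the variant-sites frame.

    Requires exactly two samples with AD; multi-allelic records are skipped
    (their count reported in a warning); missing QUAL ('.') becomes 0 so the
    quality filter removes such sites.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 2:
        raise ValueError(f"pooled VCF must have exactly 2 samples, found {len(vcf.samples)}")
    rows = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} lacks the AD format field")
        qual = rec.QUAL if rec.QUAL is not None else 0.0
        rows.append(
            (
                normalize_chrom(rec.CHROM),
                rec.POS,
                max(int(ad[0][0]), 0),
                max(int(ad[0][1]), 0),
                max(int(ad[1][0]), 0),
                max(int(ad[1][1]), 0),
                float(qual),
            )
        )
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic records")
    return pd.DataFrame(rows, columns=POOL_TSV_COLUMNS)


def read_parental_vcf(path) -> pd.DataFrame:
    """Read parental genotypes (GT required) into chrom, pos, gt_p1, gt_p2, ...

    Alt-allele dosages per sample; multi-allelic records skipped with a
    warning; missing genotypes coded -1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        doses = []
        for gt in rec.genotypes:
            alleles = [a for a in gt[:-1] if a >= 0]
            doses.append(sum(alleles) if alleles else -1)
        rows.append((normalize_chrom(rec.CHROM), rec.POS, *doses))
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic records")
    cols = ["chrom", "pos"] + [f"gt_p{i + 1}" for i in range(len(samples))]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# gene annotation


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene locations from BED (4+ columns, 0-based half-open) or TSV.

    TSV needs columns ``gene_id, chrom, start`` (1-based, stored verbatim).
    BED start coordinates are converted to 1-based.  Duplicate gene ids are
    an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        frame = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "bed_start", "bed_end", "gene_id"], usecols=range(4),
            dtype={"chrom": str},
        )
        if (frame["bed_start"] < 0).any():
            raise ValueError("negative BED start coordinate")
        if (frame["bed_end"] <= frame["bed_start"]).any():
            raise ValueError("BED end must exceed start (half-open intervals)")
        out = pd.DataFrame(
            {
                "gene_id": frame["gene_id"],
                "chrom": frame["chrom"].map(normalize_chrom),
                "start": frame["bed_start"] + 1,
            }
        )
    else:
        out = read_tsv(path, dtype={"chrom": str})
        required = {"gene_id", "chrom", "start"}
        if not required.issubset(out.columns):
            raise ValueError(f"gene TSV must carry columns {sorted(required)}")
        out = out[["gene_id", "chrom", "start"]].copy()
        out["chrom"] = out["chrom"].map(normalize_chrom)
    dup = out["gene_id"][out["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene ids: {sorted(dup.unique())[:10]}")
    return out.set_index("gene_id")


def write_gene_bed(annotation: pd.DataFrame, path, feature_length: int = 1):
    """Write gene starts as BED intervals (internal 1-based -> 0-based half-open)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gene, row in annotation.iterrows():
            start0 = int(row["start"]) - 1
            fh.write(f"{row['chrom']}\t{start0}\t{start0 + feature_length}\t{gene}\n")


# ---------------------------------------------------------------------------
# counts, designs, results


def write_counts(counts: pd.DataFrame, path, **meta):
    frame = counts.copy()
    frame.index.name = "gene_id"
    write_tsv(frame, path, stage="counts", index=True, **meta)


def read_counts(path) -> pd.DataFrame:
    return read_tsv(path, index_col=0)


def read_design(path) -> pd.Series:
    """Sample -> group mapping from a two-column TSV (sample, group)."""
    frame = read_tsv(path)
    cols = list(frame.columns[:2])
    return frame.set_index(cols[0])[cols[1]]


def read_chrom_lengths(path) -> dict:
    frame = read_tsv(path, dtype={0: str})
    cols = list(frame.columns[:2])
    return {
        normalize_chrom(c): int(l)
        for c, l in zip(frame[cols[0]], frame[cols[1]])
    }


def write_de_results(results: pd.DataFrame, annotation: pd.DataFrame | None, path, **meta):
    """DE results TSV with gene location columns always included.

    Emitting chromosome and start alongside every gene makes linked-ASE
    candidates visible at a glance — genes on the mutant chromosome are
    immediately identifiable in the output.
    """
    out = results.copy()
    if annotation is not None:
        ann = annotation.reindex(out.index)
        out.insert(0, "chrom", ann["chrom"])
        out.insert(1, "start", ann["start"])
    out.index.name = "gene_id"
    write_tsv(out, path, stage="de-results", index=True, **meta)


def read_de_results(path) -> pd.DataFrame:
    """Import a DE results table (ours or an external caller's).

    Needs at minimum a gene id index and ``padj`` or ``de``; recognises
    DESeq2-style column names (log2FoldChange, pvalue, padj).
    """
    frame = read_tsv(path, index_col=0)
    renames = {"log2FoldChange": "log2fc", "lfcSE": "se", "pvalue": "pvalue", "padj": "padj"}
    frame = frame.rename(columns=renames)
    if "de" not in frame.columns:
        if "padj" not in frame.columns:
            raise ValueError("DE results need a 'de' flag or a 'padj' column")
        frame["de"] = frame["padj"].fillna(1.0) < 0.05
    frame["de"] = frame["de"].astype(bool)
    return frame


def read_go_annotation(path) -> pd.DataFrame:
    frame = read_tsv(path)
    cols = list(frame.columns[:2])
    out = frame[cols].copy()
    out.columns = ["gene_id", "term_id"]
    return out
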