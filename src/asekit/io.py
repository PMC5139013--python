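"""Readers and writers for the pipeline's plain-text table formats.

Genotypes travel either as a minimal VCF (GT field only) or as a TSV matrix
(rows = SNPs, columns = individuals, values 0/1/2 and NA for missing);
counts, panels, truth ledgers and sample sheets are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .simulate import MISSING

__all__ = [
    "write_counts_tsv", "read_counts_tsv",
    "write_genotypes_tsv", "read_genotypes_tsv",
    "write_genotypes_vcf", "read_genotypes_vcf",
    "write_panel_tsv", "read_panel_tsv",
    "write_samples_tsv", "read_samples_tsv",
    "write_json",
]

COUNT_COLUMNS = ["snp_id", "individual_id", "tissue", "timepoint",
                 "ref_count", "alt_count", "other_count"]


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in COUNT_COLUMNS if c in counts.columns]
    counts[cols].to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str, "individual_id": str})


def write_genotypes_tsv(genotypes: pd.DataFrame, path: str | Path) -> None:
    out = genotypes.astype(object).where(genotypes != MISSING, "NA")
    out.to_csv(path, sep="\t", index_label="snp_id")


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    g = pd.read_csv(path, sep="\t", index_col="snp_id", na_values="NA")
    return g.fillna(MISSING).astype(np.int8)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_INV = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
           "1/1": 2, "1|1": 2, "./.": MISSING, ".|.": MISSING, ".": MISSING}


def write_genotypes_vcf(genotypes: pd.DataFrame, panel: pd.DataFrame,
                        path: str | Path) -> None:
    """Minimal VCF 4.2 with only the GT field, 1-based positions."""
    panel = panel.set_index("snp_id") if "snp_id" in panel.columns else panel
    inds = list(genotypes.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.loc[genotypes.index, "chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(inds) + "\n")
        for sid in genotypes.index:
            row = panel.loc[sid]
            gts = "\t".join(_GT[int(genotypes.at[sid, ind])] for ind in inds)
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{sid}\t{row['ref']}\t"
                     f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n")


def read_genotypes_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a VCF's GT fields into a SNP x individual matrix plus panel."""
    rows, panel_rows = [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            sid = rec.id or f"{rec.chrom}:{rec.pos}"
            alt = rec.alts[0] if rec.alts else "."
            panel_rows.append((sid, rec.chrom, rec.pos, rec.ref, alt, 1.0))
            geno = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    geno.append(MISSING)
                else:
                    geno.append(int(sum(gt)))
            rows.append(geno)
    genotypes = pd.DataFrame(rows, columns=samples,
                             index=[r[0] for r in panel_rows]).astype(np.int8)
    genotypes.index.name = "snp_id"
    panel = pd.DataFrame(panel_rows,
                         columns=["snp_id", "chrom", "pos", "ref", "alt", "mappability"])
    return genotypes, panel


def write_panel_tsv(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})


def write_samples_tsv(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
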