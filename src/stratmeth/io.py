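"""Readers and writers for the pipeline's plain-text formats.

Genotypes travel as a pair of TSVs (variant metadata + dosage matrix),
methylation as a probes x samples beta TSV plus a manifest TSV, GWAS
summary statistics as the conventional SNP/CHR/BP/A1/A2/BETA/SE/P[,INFO,
MAF] table.  Chromosome positions are 1-based throughout, matching .bim
convention.  Gene sets are GMT; ground truth is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MethMatrix, SnpPanel, check_summary

GWAS_WRITE_COLS = {
    "chrom": "CHR", "pos": "BP", "a1": "A1", "a2": "A2",
    "beta": "BETA", "se": "SE", "p": "P", "info": "INFO", "maf": "MAF",
}
GWAS_READ_COLS = {v: k for k, v in GWAS_WRITE_COLS.items()}


def write_snp_panel(panel: SnpPanel, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.variants.tsv`` and ``<prefix>.dosage.tsv``."""
    prefix = Path(prefix)
    vpath = prefix.with_suffix(".variants.tsv")
    dpath = prefix.with_suffix(".dosage.tsv")
    panel.variants.rename_axis("snp").to_csv(vpath, sep="\t")
    panel.dosages.rename_axis("sample").to_csv(dpath, sep="\t")
    return vpath, dpath


def read_snp_panel(prefix) -> SnpPanel:
    prefix = Path(prefix)
    variants = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t",
                           index_col="snp")
    dosages = pd.read_csv(prefix.with_suffix(".dosage.tsv"), sep="\t",
                          index_col="sample")
    dosages.columns.name = variants.index.name
    return SnpPanel(variants, dosages)


def write_gwas_summary(summary: pd.DataFrame, path) -> Path:
    out = summary.rename(columns=GWAS_WRITE_COLS)
    out.index.name = "SNP"
    out.to_csv(path, sep="\t")
    return Path(path)


def read_gwas_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="SNP")
    df = df.rename(columns=GWAS_READ_COLS)
    df.index.name = "snp"
    return check_summary(df)


def write_meth_matrix(meth: MethMatrix, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.beta.tsv`` and ``<prefix>.manifest.tsv``."""
    prefix = Path(prefix)
    bpath = prefix.with_suffix(".beta.tsv")
    mpath = prefix.with_suffix(".manifest.tsv")
    meth.beta.rename_axis("probe").to_csv(bpath, sep="\t",
                                          float_format="%.6g")
    meth.manifest.rename_axis("probe").to_csv(mpath, sep="\t")
    return bpath, mpath


def read_meth_matrix(prefix) -> MethMatrix:
    prefix = Path(prefix)
    beta = pd.read_csv(prefix.with_suffix(".beta.tsv"), sep="\t",
                       index_col="probe")
    manifest = pd.read_csv(prefix.with_suffix(".manifest.tsv"), sep="\t",
                           index_col="probe")
    beta = beta.clip(1e-6, 1 - 1e-6)
    return MethMatrix(beta, manifest)


def write_sample_sheet(samples: pd.DataFrame, path) -> Path:
    samples.rename_axis("sample").to_csv(path, sep="\t")
    return Path(path)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path) -> Path:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
    return Path(path)


def read_gene_models(path) -> pd.DataFrame:
    """TSV with columns gene, chrom, strand, tss, start, end (1-based)."""
    return pd.read_csv(path, sep="\t")


def write_truth_json(truth, path) -> Path:
    """Serialize the ground-truth object (pandas fields become records)."""
    def convert(v):
        if isinstance(v, pd.Series):
            return v.to_dict()
        if isinstance(v, pd.DataFrame):
            return v.to_dict(orient="index")
        if isinstance(v, (np.ndarray, pd.Index)):
            return list(v)
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        return v

    payload = {k: convert(v) for k, v in vars(truth).items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, default=convert)
    return Path(path)
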