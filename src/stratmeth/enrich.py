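"""Gene mapping of differentially methylated probes and hypergeometric
gene-set enrichment.

Probes map to genes physically (within the gene body) and/or through
regulatory domains built basal-plus-extension style: a basal window of
5 kb upstream / 1 kb downstream of the TSS (strand-aware), extended
outward up to a distal limit but never into a neighbouring gene's basal
domain.  Enrichment is a one-sided hypergeometric upper-tail test per
gene set with BH correction across sets.

Coordinates are 1-based inclusive at file boundaries and in the public
API; domain intervals are closed [start, end].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_fdr

logger = logging.getLogger(__name__)

GENE_COLUMNS = ("gene", "chrom", "strand", "tss", "start", "end")


@dataclass
class RegulatoryDomain:
    gene: str
    chrom: object
    basal_start: int
    basal_end: int
    start: int
    end: int


def _check_genes(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene model frame missing columns: {missing}")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene start must be <= end")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    genes = genes.copy()
    dup = genes.duplicated(subset=["gene", "chrom"], keep=False)
    if dup.any():
        warnings.warn("duplicate gene symbols per chromosome; suffixing")
        counts: dict = {}
        new = []
        for g, d in zip(genes["gene"], dup):
            if d:
                counts[g] = counts.get(g, 0) + 1
                new.append(f"{g}_{counts[g]}")
            else:
                new.append(g)
        genes["gene"] = new
    return genes


def build_domains(
    genes: pd.DataFrame,
    basal_up: int = 5000,
    basal_down: int = 1000,
    distal: int = 5000,
) -> pd.DataFrame:
    """Basal-plus-extension regulatory domains.

    Basal = [TSS - basal_up, TSS + basal_down] on the + strand (mirrored
    on -).  Each domain extends outward up to ``distal`` bp but stops at a
    neighbouring gene's basal edge; coordinates are clipped at 1.
    Returns a frame with gene, chrom, basal_start/end, start/end.
    """
    genes = _check_genes(genes)
    rows = []
    for chrom, sub in genes.groupby("chrom", sort=False):
        basal = []
        for _, g in sub.iterrows():
            if g["strand"] == "+":
                bs, be = g["tss"] - basal_up, g["tss"] + basal_down
            else:
                bs, be = g["tss"] - basal_down, g["tss"] + basal_up
            basal.append((g["gene"], max(int(bs), 1), max(int(be), 1)))
        basal.sort(key=lambda t: (t[1], t[2]))
        for i, (name, bs, be) in enumerate(basal):
            left_limit = max(bs - distal, 1)
            for j in range(i - 1, -1, -1):
                if basal[j][2] >= bs:  # overlapping basal: no room to extend
                    left_limit = bs
                    break
                left_limit = max(left_limit, basal[j][2] + 1)
                break
            right_limit = be + distal
            for j in range(i + 1, len(basal)):
                if basal[j][1] <= be:
                    right_limit = be
                    break
                right_limit = min(right_limit, basal[j][1] - 1)
                break
            rows.append((name, chrom, bs, be, left_limit, right_limit))
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "basal_start", "basal_end",
                       "start", "end"]
    )


def map_probes(
    dmps: pd.DataFrame,
    genes: pd.DataFrame,
    domains: pd.DataFrame | None = None,
    mode: str = "union",
) -> tuple[pd.DataFrame, list]:
    """Map probes (frame with ``chrom``/``pos``, indexed by probe id) to genes.

    mode "physical": probe within the gene body; "regulatory": probe within
    a regulatory domain; "union": either, deduplicated.  A probe may map to
    several genes; all pairs are retained.  Returns (probe->gene pairs with
    the mapping mode, unique gene list).
    """
    if mode not in {"physical", "regulatory", "union"}:
        raise ValueError(f"unknown mapping mode {mode!r}")
    genes = _check_genes(genes)
    if domains is None and mode != "physical":
        domains = build_domains(genes)
    pairs = []
    if mode in {"physical", "union"}:
        for _, g in genes.iterrows():
            hit = dmps.index[
                (dmps["chrom"] == g["chrom"])
                & (dmps["pos"] >= g["start"])
                & (dmps["pos"] <= g["end"])
            ]
            pairs.extend((p, g["gene"], "physical") for p in hit)
    if mode in {"regulatory", "union"}:
        for _, d in domains.iterrows():
            hit = dmps.index[
                (dmps["chrom"] == d["chrom"])
                & (dmps["pos"] >= d["start"])
                & (dmps["pos"] <= d["end"])
            ]
            pairs.extend((p, d["gene"], "regulatory") for p in hit)
    table = pd.DataFrame(pairs, columns=["probe", "gene", "mode"])
    table = table.drop_duplicates(subset=["probe", "gene", "mode"])
    mapped_frac = table["probe"].nunique() / max(len(dmps), 1)
    if len(dmps) >= 10 and mapped_frac < 0.5:
        warnings.warn(
            f"only {mapped_frac:.0%} of probes mapped; check genome assembly"
        )
    gene_list = sorted(table["gene"].unique())
    return table, gene_list


def enrich(
    query_genes,
    gene_sets: dict,
    background_genes,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene list in each set.

    ``gene_sets`` maps set name -> iterable of genes (GMT-style); sets are
    intersected with the background, the query must be a subset of the
    background.  Returns a frame sorted by BH-adjusted p with overlap,
    set/background sizes, p and q.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background")
    query = set(query_genes)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    n_bg = len(background)
    n_q = len(query)
    rows = []
    for name, members in gene_sets.items():
        in_bg = set(members) & background
        k = len(in_bg & query)
        # P(X >= k) with X ~ Hypergeom(N=n_bg, K=|set|, n=n_q)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(in_bg), n_q))
        rows.append((name, k, len(in_bg), p))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    table["background_size"] = n_bg
    table["query_size"] = n_q
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    return table.sort_values(["q", "p"]).set_index("set")
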