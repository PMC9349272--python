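"""Core in-memory containers shared across pipeline stages.

All containers are thin dataclasses around pandas objects with the column
contracts documented per field.  Genotype dosages count copies of allele A1
and may be fractional (imputed-dosage mode); methylation is stored as beta
values in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns required in the per-variant metadata frame.
VARIANT_COLUMNS = ("chrom", "pos", "a1", "a2", "maf", "info")

#: Columns required in a GWAS summary-statistics frame.
SUMMARY_COLUMNS = ("chrom", "pos", "a1", "a2", "beta", "se", "p")

#: Columns required in a probe manifest.
MANIFEST_COLUMNS = ("chrom", "pos", "gene", "probe_snp")


@dataclass
class SnpPanel:
    """Genotype dosages plus variant metadata.

    Parameters
    ----------
    variants
        DataFrame indexed by variant id with columns ``chrom`` (str/int),
        ``pos`` (1-based int), ``a1``, ``a2`` (single-letter alleles),
        ``maf`` (minor-allele frequency in [0, 0.5]) and ``info``
        (imputation quality in [0, 1]).
    dosages
        DataFrame of A1-allele dosages in [0, 2], samples x variants.
        ``NaN`` marks a missing genotype.
    """

    variants: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant frame missing columns: {missing}")
        if not self.variants.index.is_unique:
            raise ValueError("variant ids must be unique")
        if not self.variants.index.equals(self.dosages.columns):
            self.dosages = self.dosages.loc[:, self.variants.index]
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")
        maf = self.variants["maf"].to_numpy(dtype=float)
        if np.any((maf < -1e-12) | (maf > 0.5 + 1e-12)):
            raise ValueError("MAF must lie in [0, 0.5]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, ids) -> "SnpPanel":
        ids = pd.Index(ids)
        return SnpPanel(self.variants.loc[ids], self.dosages.loc[:, ids])

    def subset_samples(self, ids) -> "SnpPanel":
        ids = pd.Index(ids)
        return SnpPanel(self.variants, self.dosages.loc[ids])


def check_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Validate a GWAS summary frame (indexed by SNP id)."""
    missing = [c for c in SUMMARY_COLUMNS if c not in summary.columns]
    if missing:
        raise ValueError(f"summary frame missing columns: {missing}")
    p = summary["p"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("summary p-values must lie in (0, 1]")
    ok = summary["a1"].isin(list("ACGT")) & summary["a2"].isin(list("ACGT"))
    if not ok.all():
        raise ValueError("summary alleles must be in {A,C,G,T}")
    return summary


@dataclass
class MethMatrix:
    """Methylation beta values (probes x samples) with a probe manifest.

    ``manifest`` is indexed by probe id with columns ``chrom``, ``pos``
    (1-based), ``gene`` (comma-separated annotation, may be empty) and
    ``probe_snp`` (bool: SNP within 50 bp of the interrogated site).
    Optional manifest columns ``blood_variable`` (bool) and
    ``blood_brain_r`` (float) carry the external reference annotations.
    """

    beta: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.is_unique:
            raise ValueError("probe ids must be unique")
        missing = [c for c in MANIFEST_COLUMNS if c not in self.manifest.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        extra = self.beta.index.difference(self.manifest.index)
        if len(extra):
            raise ValueError(f"{len(extra)} probes absent from manifest")
        vals = self.beta.to_numpy(dtype=float)
        if np.any((vals <= 0) | (vals >= 1)):
            raise ValueError("beta values must lie strictly in (0, 1)")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    def subset_probes(self, ids) -> "MethMatrix":
        ids = pd.Index(ids)
        return MethMatrix(self.beta.loc[ids], self.manifest.loc[ids])

    def subset_samples(self, ids) -> "MethMatrix":
        return MethMatrix(self.beta.loc[:, pd.Index(ids)], self.manifest)


@dataclass
class EwasTable:
    """Per-probe EWAS results plus the global empirical-null summary.

    ``table`` is indexed by probe id with columns ``coef`` (M-value units
    per stratum unit), ``se``, ``t``, ``p`` (raw), ``z``, ``z_corr``,
    ``p_corr`` (bias/inflation corrected), ``q`` (BH FDR on corrected p).
    """

    table: pd.DataFrame
    bias: float
    inflation: float
    bonferroni: float
    n_sv: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def n_probes(self) -> int:
        return len(self.table)

    def significant(self, corrected: bool = True) -> pd.Index:
        p = self.table["p_corr" if corrected else "p"]
        return self.table.index[p < self.bonferroni]
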