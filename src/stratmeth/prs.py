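"""Genotype QC, relatedness/ancestry handling, and clumping + thresholding
polygenic scores with p-value-threshold optimization.

Conventions follow the standard C+T tooling: clumping window 250 kb at
r2 0.1, average-per-allele scores (sum of effect x dosage over 2m SNPs),
missing dosages imputed as 2*MAF, and Nagelkerke pseudo-R2 for threshold
selection.  Relatedness uses method-of-moments IBD from IBS counts;
ancestry components come from classical MDS of the IBS distance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import SnpPanel, check_summary

logger = logging.getLogger(__name__)

#: Default p-value-threshold grid; includes the conventional optima
#: reported for bipolar (0.105), depression (0.017) and cross-disorder
#: (0.229) scores so those configurations are directly reproducible.
DEFAULT_PT_GRID = (5e-8, 1e-5, 1e-4, 0.001, 0.005, 0.017, 0.05, 0.105, 0.229, 0.5, 1.0)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


@dataclass
class PrsResult:
    """Per-sample raw and standardized polygenic scores."""

    scores: pd.DataFrame  # columns: raw, std
    p_threshold: float
    n_snps_included: int
    ref_mean: float
    ref_sd: float
    nagelkerke_r2: float | None = None


@dataclass
class RelatednessReport:
    pairs: pd.DataFrame  # columns: id1, id2, pi_hat
    exclusions: list


@dataclass
class NnOutlierReport:
    stats: pd.DataFrame  # columns: mean_nn_dist, z
    exclusions: list


def filter_variants(
    panel: SnpPanel,
    summary: pd.DataFrame,
    maf_min: float = 0.05,
    info_min: float = 0.8,
    drop_ambiguous: bool = True,
) -> tuple[SnpPanel, pd.DataFrame, pd.DataFrame]:
    """Intersect panel and summary, match alleles, and apply MAF/INFO filters.

    Returns (filtered panel aligned to summary A1, filtered summary, log of
    dropped variants with reasons).  When panel A1/A2 are swapped relative
    to the summary, the dosage is flipped to 2 - d so it counts the summary
    effect allele; the effect sign is untouched.  Boundary values are
    retained (MAF = maf_min and INFO = info_min pass).  Unresolvable allele
    pairs are dropped with a logged reason, never an exception.
    """
    check_summary(summary)
    shared = panel.variants.index.intersection(summary.index)
    dropped: list[tuple[str, str]] = []
    dropped.extend((sid, "absent_in_summary")
                   for sid in panel.variants.index.difference(summary.index))
    keep = []
    flip = []
    for sid in shared:
        pa1, pa2 = panel.variants.at[sid, "a1"], panel.variants.at[sid, "a2"]
        sa1, sa2 = summary.at[sid, "a1"], summary.at[sid, "a2"]
        if drop_ambiguous and (_is_ambiguous(pa1, pa2) or _is_ambiguous(sa1, sa2)):
            dropped.append((sid, "strand_ambiguous"))
            continue
        if (pa1, pa2) == (sa1, sa2):
            flip.append(False)
        elif (pa1, pa2) == (sa2, sa1):
            flip.append(True)
        else:
            dropped.append((sid, "allele_mismatch"))
            continue
        keep.append(sid)
    keep = pd.Index(keep)
    flip = np.asarray(flip, dtype=bool)
    variants = panel.variants.loc[keep].copy()
    dosages = panel.dosages.loc[:, keep].copy()
    if flip.any():
        cols = keep[flip]
        dosages.loc[:, cols] = 2.0 - dosages.loc[:, cols]
        variants.loc[cols, ["a1", "a2"]] = variants.loc[cols, ["a2", "a1"]].to_numpy()
    maf = variants["maf"].to_numpy()
    info = (
        summary.loc[keep, "info"].to_numpy()
        if "info" in summary.columns
        else variants["info"].to_numpy()
    )
    ok = (maf >= maf_min) & (info >= info_min)
    for sid, bad_maf, bad_info in zip(keep, maf < maf_min, info < info_min):
        if bad_maf:
            dropped.append((sid, "maf_below_min"))
        elif bad_info:
            dropped.append((sid, "info_below_min"))
    keep = keep[ok]
    log = pd.DataFrame(dropped, columns=["snp", "reason"])
    if len(log):
        logger.info("filter_variants dropped %d variants (%s)", len(log),
                    log["reason"].value_counts().to_dict())
    out_panel = SnpPanel(variants.loc[keep], dosages.loc[:, keep])
    return out_panel, summary.loc[keep], log


def ld_clump(
    panel: SnpPanel,
    summary: pd.DataFrame,
    window_kb: float = 250.0,
    r2_max: float = 0.1,
) -> list:
    """Greedy LD clumping: retain index SNPs by ascending p, remove
    correlated neighbours (r2 > r2_max within window_kb).

    Ties in p are broken by genomic position (lower chromosome, then lower
    position, retained first).  Returns retained variant ids in the panel's
    original order.
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    v = panel.variants
    order = sorted(
        v.index,
        key=lambda sid: (summary.at[sid, "p"], v.at[sid, "chrom"], v.at[sid, "pos"]),
    )
    window = window_kb * 1000.0
    dos = panel.dosages.to_numpy(dtype=float)
    col = {sid: i for i, sid in enumerate(v.index)}
    chrom = v["chrom"].to_dict()
    pos = v["pos"].to_dict()
    removed: set = set()
    retained: list = []
    for sid in order:
        if sid in removed:
            continue
        retained.append(sid)
        for other in v.index:
            if other == sid or other in removed or other in retained:
                continue
            if chrom[other] != chrom[sid]:
                continue
            if abs(pos[other] - pos[sid]) > window:
                continue
            x, y = dos[:, col[sid]], dos[:, col[other]]
            sx, sy = x.std(), y.std()
            r2 = 0.0 if sx == 0 or sy == 0 else float(np.corrcoef(x, y)[0, 1] ** 2)
            if r2 > r2_max:
                removed.add(other)
    retained_set = set(retained)
    return [sid for sid in v.index if sid in retained_set]


def score_prs(
    panel: SnpPanel,
    summary: pd.DataFrame,
    p_threshold: float,
    ref_mean: float | None = None,
    ref_sd: float | None = None,
    average: bool = True,
) -> PrsResult:
    """C+T polygenic score at one p-value threshold.

    raw_i = (1/(2m)) * sum_{j: p_j < p_T} beta_j * dosage_ij with m the
    number of included SNPs (set ``average=False`` for the raw sum).
    Missing dosages are imputed as 2*MAF.  Standardization uses the given
    reference mean/SD, defaulting to this cohort's own.
    """
    sel = summary.index[summary["p"] < p_threshold].intersection(
        panel.variants.index
    )
    if len(sel) == 0:
        raise ValueError(f"no SNPs pass p_T={p_threshold!r}")
    dos = panel.dosages.loc[:, sel].to_numpy(dtype=float)
    maf = panel.variants.loc[sel, "maf"].to_numpy()
    nan = np.isnan(dos)
    if nan.any():
        dos = np.where(nan, (2.0 * maf)[None, :], dos)
    beta = summary.loc[sel, "beta"].to_numpy()
    raw = dos @ beta
    if average:
        raw = raw / (2.0 * len(sel))
    mean = float(raw.mean()) if ref_mean is None else float(ref_mean)
    sd = float(raw.std(ddof=0)) if ref_sd is None else float(ref_sd)
    std = (raw - mean) / sd if sd > 0 else raw - mean
    scores = pd.DataFrame({"raw": raw, "std": std}, index=panel.sample_ids)
    return PrsResult(scores, p_threshold, int(len(sel)), mean, sd)


def nagelkerke_r2(ll_full: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R2 from full/null log-likelihoods."""
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll_null - ll_full))
    max_r2 = 1.0 - np.exp((2.0 / n) * ll_null)
    return float(cox_snell / max_r2) if max_r2 > 0 else 0.0


def optimize_threshold(
    panel: SnpPanel,
    summary: pd.DataFrame,
    phenotype: pd.Series,
    grid=DEFAULT_PT_GRID,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pick the p_T maximising Nagelkerke pseudo-R2 of phenotype ~ PRS.

    Samples with missing phenotype (e.g. high-risk participants coded
    unknown) are excluded from the logistic fit.  Thresholds with no
    passing SNPs or a separated fit are skipped and recorded as NaN.
    """
    pheno = phenotype.dropna()
    samples = pheno.index.intersection(panel.sample_ids)
    pheno = pheno.loc[samples].astype(float)
    rows = []
    for p_t in grid:
        try:
            res = score_prs(panel, summary, p_t)
        except ValueError:
            rows.append((p_t, 0, np.nan, np.nan))
            continue
        x = res.scores.loc[samples, "std"].to_numpy()[:, None]
        if covariates is not None:
            x = np.hstack([x, covariates.loc[samples].to_numpy(dtype=float)])
        X = sm.add_constant(x, has_constant="add")
        try:
            fit = sm.Logit(pheno.to_numpy(), X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.params)):
                raise ValueError("non-finite estimates")
            r2 = nagelkerke_r2(fit.llf, fit.llnull, len(pheno))
            pval = float(fit.pvalues[1])
        except Exception as exc:  # separation and friends: skip, don't die
            logger.warning("p_T=%g skipped: %s", p_t, exc)
            rows.append((p_t, res.n_snps_included, np.nan, np.nan))
            continue
        rows.append((p_t, res.n_snps_included, r2, pval))
    profile = pd.DataFrame(rows, columns=["p_t", "n_snps", "r2", "p_value"])
    if profile["r2"].isna().all():
        raise ValueError("no p_T in the grid produced a valid fit")
    best = float(profile.loc[profile["r2"].idxmax(), "p_t"])
    return best, profile


# ---------------------------------------------------------------------------
# relatedness and ancestry
# ---------------------------------------------------------------------------

def _ibs_shares(dosages: np.ndarray) -> np.ndarray:
    """n x n matrix of summed IBS allele shares (0..2 per variant)."""
    n = dosages.shape[0]
    shares = np.empty((n, n))
    for i in range(n):
        shares[i] = (2.0 - np.abs(dosages - dosages[i])).sum(axis=1)
    return shares


def ibs_distance_matrix(panel: SnpPanel) -> pd.DataFrame:
    """IBS distance = 1 - (allele shares / 2 * n_snps), pairwise."""
    dos = np.nan_to_num(panel.dosages.to_numpy(dtype=float), nan=1.0)
    d = 1.0 - _ibs_shares(dos) / (2.0 * panel.n_snps)
    return pd.DataFrame(d, index=panel.sample_ids, columns=panel.sample_ids)


def relatedness_filter(panel: SnpPanel, pi_hat_max: float = 0.1) -> RelatednessReport:
    """Method-of-moments IBD (pi_hat) from IBS counts; flag related pairs.

    For each pair with pi_hat >= pi_hat_max the member with more missing
    genotypes is listed for exclusion (tie: the later sample id).
    """
    if panel.n_samples < 2:
        raise ValueError("need >= 2 samples")
    dos_raw = panel.dosages.to_numpy(dtype=float)
    freq = np.nanmean(dos_raw, axis=0) / 2.0
    poly = (freq > 0) & (freq < 1)
    if not poly.any():
        raise ValueError("IBD undefined: all variants are monomorphic")
    dos = np.nan_to_num(dos_raw[:, poly], nan=np.round(2 * freq[poly]))
    p = freq[poly]
    q = 1.0 - p
    # expected IBS-class probabilities for unrelated (Z0) / one-shared (Z1)
    e0_z0 = (2 * p**2 * q**2).mean()
    e1_z0 = (4 * p**3 * q + 4 * p * q**3).mean()
    e1_z1 = (2 * p * q).mean()
    m = dos.shape[1]
    n = dos.shape[0]
    ids = panel.sample_ids
    miss = np.isnan(dos_raw).sum(axis=1)
    rows = []
    exclusions: set = set()
    for i in range(n):
        diff = np.abs(dos[i + 1:] - dos[i])
        n0 = (diff == 2).sum(axis=1) / m
        n1 = (diff == 1).sum(axis=1) / m
        z0 = n0 / e0_z0
        z1 = (n1 - z0 * e1_z0) / e1_z1
        z0 = np.clip(z0, 0, 1)
        z1 = np.clip(z1, 0, 1 - z0)
        z2 = 1.0 - z0 - z1
        pi = np.clip(z2 + 0.5 * z1, 0, 1)
        for k, j in enumerate(range(i + 1, n)):
            rows.append((ids[i], ids[j], float(pi[k])))
            if pi[k] >= pi_hat_max:
                if miss[i] != miss[j]:
                    drop = ids[i] if miss[i] > miss[j] else ids[j]
                else:
                    drop = max(ids[i], ids[j])
                exclusions.add(drop)
    pairs = pd.DataFrame(rows, columns=["id1", "id2", "pi_hat"])
    return RelatednessReport(pairs, sorted(exclusions))


def mds_ancestry(panel: SnpPanel, k: int = 4) -> pd.DataFrame:
    """Classical MDS of the IBS distance matrix: top-k components
    (eigenvectors scaled by sqrt eigenvalue), each centred at 0."""
    n = panel.n_samples
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    d = ibs_distance_matrix(panel).to_numpy()
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    comps = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return pd.DataFrame(comps, index=panel.sample_ids,
                        columns=[f"C{i + 1}" for i in range(k)])


def ibs_nn_outliers(
    panel: SnpPanel, n_neighbours: int = 4, z_max: float = 4.0
) -> NnOutlierReport:
    """Flag ancestry outliers by mean IBS distance to the nearest neighbours.

    The per-sample statistic is the mean distance to its ``n_neighbours``
    nearest neighbours; Z-scores are taken over samples and Z > z_max is
    excluded.
    """
    n = panel.n_samples
    if n <= 5:
        raise ValueError("need more than 5 samples")
    d = ibs_distance_matrix(panel).to_numpy()
    k = min(n_neighbours, n - 1)
    stat = np.sort(d, axis=1)[:, 1:k + 1].mean(axis=1)
    z = (stat - stat.mean()) / stat.std(ddof=1)
    stats = pd.DataFrame({"mean_nn_dist": stat, "z": z}, index=panel.sample_ids)
    excl = list(stats.index[stats["z"] > z_max])
    return NnOutlierReport(stats, excl)
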