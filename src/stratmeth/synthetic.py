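"""Synthetic cohort generator with known ground truth.

Emulates the data-generating structure the downstream analysis assumes:
LD-blocked biallelic genotypes (latent-Gaussian copula), GWAS summary
statistics from a large external case-control study with planted causal
effects, beta-valued methylation built on the logit scale from a bimodal
baseline plus cell-composition, batch, smoking and polygenic-score
coupling terms, and liability-threshold phenotypes with family structure.

Every operation takes an explicit seed or generator; there is no global
RNG state.  Identical seed + config gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .containers import MethMatrix, SnpPanel, check_summary

#: Probe id of the smoking-sentinel CpG (AHRR); beta < 0.75 flags a probable smoker.
SMOKING_PROBE = "cg05575921"

#: Six leukocyte types of the blood reference profile.
DEFAULT_CELL_TYPES = ("Bcell", "CD4T", "CD8T", "Gran", "Mono", "NK")

# Dirichlet concentration ~ typical blood fractions (B 5%, CD4T 15%, CD8T 10%,
# granulocytes 55%, monocytes 8%, NK 7%) times a concentration of 50.
DEFAULT_DIRICHLET_ALPHA = (2.5, 7.5, 5.0, 27.5, 4.0, 3.5)


@dataclass
class CohortConfig:
    """Tunable parameters of the synthetic study.

    Defaults mirror the discovery design: 103 high-risk participants
    (yielding 41/41 quintile strata), 5,000 CpG probes of which 50 are
    coupled to the standardized polygenic score with a 0.4 logit-unit
    shift per SD, six blood cell types, and a liability-scale SNP
    heritability of 0.25.
    """

    n_samples: int = 103
    n_snps: int = 1200
    n_blocks: int = 60
    block_rho: float = 0.7
    maf_range: tuple = (0.05, 0.5)
    n_causal_snps: int = 40
    effect_sd: float = 0.12
    h2_liability: float = 0.25
    gwas_n: int = 50_000
    n_probes: int = 5000
    n_coupled_probes: int = 50
    coupling_effect: float = 0.4
    noise_sd: float = 0.5
    cell_types: tuple = DEFAULT_CELL_TYPES
    dirichlet_alpha: tuple = DEFAULT_DIRICHLET_ALPHA
    cell_informative_frac: float = 0.15
    cell_delta_sd: float = 1.2
    batch_sd: float = 0.15
    n_batches: int = 3
    smoker_fraction: float = 0.02
    probe_snp_fraction: float = 0.05
    blood_variable_fraction: float = 0.95
    ambiguous_fraction: float = 0.0
    low_info_fraction: float = 0.0
    n_sib_pairs: int = 0
    case_threshold_q: float = 0.9
    hr_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_snps", "n_blocks", "n_probes", "gwas_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_snps // self.n_blocks < 1:
            raise ValueError("non-positive block size: n_blocks exceeds n_snps")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_causal_snps > self.n_snps:
            raise ValueError("n_causal_snps exceeds n_snps")
        if self.n_coupled_probes > self.n_probes:
            raise ValueError("n_coupled_probes exceeds n_probes")
        if len(self.dirichlet_alpha) != len(self.cell_types):
            raise ValueError("dirichlet_alpha length must match cell_types")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be positive")
        if not 0 <= self.h2_liability <= 1:
            raise ValueError("h2_liability must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrueParams:
    """Ground truth of one simulated cohort, for recovery tests."""

    causal_snp_ids: list = field(default_factory=list)
    snp_effects: pd.Series | None = None
    coupled_probe_ids: list = field(default_factory=list)
    probe_coupling: pd.Series | None = None
    cell_fractions: pd.DataFrame | None = None
    smoker: pd.Series | None = None
    liability: pd.Series | None = None
    genetic_score: pd.Series | None = None
    cell_reference: pd.DataFrame | None = None
    family_id: pd.Series | None = None


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _draw_variants(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant metadata: ids, positions in LD blocks across chromosomes, alleles, MAF."""
    m = config.n_snps
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)
    block = np.arange(m) * config.n_blocks // m  # contiguous blocks of near-equal size
    chrom = (block % 22) + 1
    # 10 kb spacing inside a block, >1 Mb gaps between blocks on a chromosome
    pos = np.empty(m, dtype=int)
    for b in np.unique(block):
        idx = np.where(block == b)[0]
        start = 1 + (b // 22) * 2_000_000
        pos[idx] = start + 10_000 * np.arange(len(idx))
    non_ambiguous = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    ambiguous = [("A", "T"), ("C", "G")]
    pairs = []
    amb = rng.random(m) < config.ambiguous_fraction
    for i in range(m):
        pool = ambiguous if amb[i] else non_ambiguous
        a1, a2 = pool[rng.integers(len(pool))]
        if rng.random() < 0.5:
            a1, a2 = a2, a1
        pairs.append((a1, a2))
    ids = [f"rs{i:06d}" for i in range(m)]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "a1": [p[0] for p in pairs],
            "a2": [p[1] for p in pairs],
            "maf": maf,
            "info": np.ones(m),
            "block": block,
        },
        index=pd.Index(ids, name="snp"),
    )


def _draw_haplotypes(
    variants: pd.DataFrame, n_hap: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Haplotype alleles via an AR(1) latent-Gaussian copula within LD blocks."""
    m = len(variants)
    z = np.empty((n_hap, m))
    block = variants["block"].to_numpy()
    for b in np.unique(block):
        idx = np.where(block == b)[0]
        e = rng.standard_normal((n_hap, len(idx)))
        zb = np.empty_like(e)
        zb[:, 0] = e[:, 0]
        for j in range(1, len(idx)):
            zb[:, j] = rho * zb[:, j - 1] + np.sqrt(1 - rho**2) * e[:, j]
        z[:, idx] = zb
    thresh = norm.ppf(variants["maf"].to_numpy())
    return (z < thresh).astype(np.int8)  # allele 1 = A1 (minor)


def simulate_genotypes(
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    variants: pd.DataFrame | None = None,
    n_samples: int | None = None,
    sample_prefix: str = "S",
) -> tuple[SnpPanel, TrueParams]:
    """Simulate dosages in {0,1,2} with within-block LD ~ ``block_rho``.

    ``variants`` may be supplied to reuse one truth (MAF spectrum, LD
    layout, causal effects drawn separately) across several cohorts.
    Sib-pairs (``config.n_sib_pairs``) share 50% of haplotypes in
    expectation: each sib draws one of two haplotypes per parent.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if variants is None:
        variants = _draw_variants(config, rng)
    n = config.n_samples if n_samples is None else n_samples
    k = config.n_sib_pairs
    if 2 * k > n:
        raise ValueError("n_sib_pairs exceeds available samples")
    n_unrel = n - 2 * k
    h = _draw_haplotypes(variants, 2 * n_unrel, config.block_rho, rng)
    dosage = h[0::2] + h[1::2]
    fam = [f"fam{i:04d}" for i in range(n_unrel)]
    if k:
        rows = [dosage]
        for pair in range(k):
            par = _draw_haplotypes(variants, 4, config.block_rho, rng)
            pick = rng.integers(0, 2, size=(2, 2))  # sib x parent
            sibs = np.stack(
                [par[pick[s, 0]] + par[2 + pick[s, 1]] for s in range(2)]
            )
            rows.append(sibs)
            fam.extend([f"sib{pair:04d}"] * 2)
        dosage = np.vstack(rows)
    sample_ids = pd.Index([f"{sample_prefix}{i:04d}" for i in range(n)], name="sample")
    panel = SnpPanel(
        variants.drop(columns="block"),
        pd.DataFrame(dosage.astype(float), index=sample_ids, columns=variants.index),
    )
    truth = TrueParams(family_id=pd.Series(fam, index=sample_ids, name="family_id"))
    truth.cell_reference = None
    panel.variants.attrs["block"] = variants["block"]
    return panel, truth


def draw_snp_effects(config: CohortConfig, variants: pd.DataFrame,
                     rng: np.random.Generator) -> pd.Series:
    """Per-SNP true log-odds effects: N(0, effect_sd) at causal SNPs, 0 elsewhere."""
    effects = pd.Series(0.0, index=variants.index, name="beta_true")
    causal = rng.choice(variants.index.to_numpy(), size=config.n_causal_snps,
                        replace=False)
    effects.loc[causal] = rng.normal(0.0, config.effect_sd, size=config.n_causal_snps)
    return effects


def simulate_gwas_summary(
    panel: SnpPanel,
    true_effects: pd.Series,
    gwas_n: int,
    rng: np.random.Generator | None = None,
    low_info_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """GWAS summary statistics with Wald noise around the true effects.

    SE = 1/sqrt(2 * MAF * (1-MAF) * gwas_n); two-sided p from the Wald z.
    INFO is drawn in [0.8, 1] except for a configurable low-INFO fraction.
    """
    if gwas_n <= 0:
        raise ValueError("gwas_n must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    v = panel.variants
    beta_true = true_effects.reindex(v.index).fillna(0.0).to_numpy()
    maf = v["maf"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * gwas_n)
    beta_hat = beta_true + rng.normal(0.0, se)
    z = beta_hat / se
    p = 2.0 * norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    info = rng.uniform(0.8, 1.0, size=len(v))
    low = rng.random(len(v)) < low_info_fraction
    info[low] = rng.uniform(0.3, 0.8, size=low.sum())
    summary = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "pos": v["pos"],
            "a1": v["a1"],
            "a2": v["a2"],
            "beta": beta_hat,
            "se": se,
            "p": p,
            "info": info,
            "maf": maf,
        },
        index=v.index,
    )
    return check_summary(summary)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def _probe_architecture(config: CohortConfig, rng: np.random.Generator) -> dict:
    """Fixed per-probe parameters shared by all cohorts drawn from one truth."""
    p = config.n_probes
    comp = rng.choice(3, size=p, p=[0.45, 0.45, 0.10])
    means = np.array([-2.2, 2.2, 0.0])
    sds = np.array([0.7, 0.7, 1.0])
    baseline = rng.normal(means[comp], sds[comp])
    n_types = len(config.cell_types)
    delta = np.zeros((p, n_types))
    informative = rng.random((p, n_types)) < config.cell_informative_frac
    delta[informative] = rng.normal(0.0, config.cell_delta_sd, size=informative.sum())
    coupled = rng.choice(p, size=config.n_coupled_probes, replace=False)
    coupling = np.zeros(p)
    coupling[coupled] = config.coupling_effect * rng.choice([-1.0, 1.0],
                                                            size=len(coupled))
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(p)], name="probe")
    manifest = pd.DataFrame(
        {
            "chrom": rng.integers(1, 23, size=p),
            "pos": rng.integers(1, 2_000_000, size=p) * 100 + 1,
            "gene": [f"GENE{i % max(p // 4, 1):05d}" for i in range(p)],
            "probe_snp": rng.random(p) < config.probe_snp_fraction,
            "blood_variable": rng.random(p) < config.blood_variable_fraction,
            "blood_brain_r": rng.uniform(-1.0, 1.0, size=p),
        },
        index=probe_ids,
    )
    # coupled probes must survive the reference filters for recovery runs
    manifest.loc[probe_ids[coupled], ["probe_snp", "blood_variable"]] = [False, True]
    reference = pd.DataFrame(
        expit(baseline[:, None] + delta),
        index=probe_ids,
        columns=list(config.cell_types),
    )
    return {
        "baseline": baseline,
        "delta": delta,
        "coupling": pd.Series(coupling, index=probe_ids, name="coupling"),
        "manifest": manifest,
        "reference": reference,
        "probe_ids": probe_ids,
    }


def simulate_methylation(
    prs: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    architecture: dict | None = None,
    batch: pd.Series | None = None,
    smoker: pd.Series | None = None,
) -> tuple[MethMatrix, TrueParams]:
    """Beta-valued methylation coupled to the standardized polygenic score.

    logit(beta) = baseline + cell-mixture term + batch effect
    + coupling * PRS_std at coupled probes + N(0, noise_sd); the smoking
    sentinel probe is set below 0.75 for smokers and >= 0.85 centrally
    for non-smokers.  ``prs`` must be standardized within the cohort.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if architecture is None:
        architecture = _probe_architecture(config, rng)
    samples = prs.index
    n = len(samples)
    prs_std = prs.to_numpy(dtype=float)
    if n > 2 and (abs(prs_std.mean()) > 0.2 or not 0.5 < prs_std.std() < 2.0):
        raise ValueError("prs must be standardized (mean 0, SD 1) within the cohort")
    fractions = rng.dirichlet(config.dirichlet_alpha, size=n)
    if batch is None:
        batch = pd.Series(rng.integers(1, config.n_batches + 1, size=n),
                          index=samples, name="batch")
    if smoker is None:
        smoker = pd.Series(rng.random(n) < config.smoker_fraction,
                           index=samples, name="smoker")
    batch_eff = rng.normal(0.0, config.batch_sd,
                           size=(config.n_batches, config.n_probes))
    logit_base = architecture["baseline"]
    delta = architecture["delta"]
    coupling = architecture["coupling"].to_numpy()
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_probes, n))
    logits = (
        logit_base[:, None]
        + delta @ fractions.T
        + batch_eff[batch.to_numpy() - 1].T
        + coupling[:, None] * prs_std[None, :]
        + noise
    )
    beta = np.clip(expit(logits), 1e-6, 1 - 1e-6)
    beta = pd.DataFrame(beta, index=architecture["probe_ids"], columns=samples)
    # smoking sentinel probe appended with its own generating rule
    smk = np.where(
        smoker.to_numpy(),
        rng.uniform(0.45, 0.70, size=n),
        np.clip(rng.normal(0.90, 0.03, size=n), 0.85, 1 - 1e-6),
    )
    beta.loc[SMOKING_PROBE] = smk
    manifest = architecture["manifest"].copy()
    manifest.loc[SMOKING_PROBE] = {
        "chrom": 5, "pos": 373378, "gene": "AHRR", "probe_snp": False,
        "blood_variable": True, "blood_brain_r": 0.0,
    }
    truth = TrueParams(
        coupled_probe_ids=list(
            architecture["coupling"].index[architecture["coupling"] != 0]
        ),
        probe_coupling=architecture["coupling"],
        cell_fractions=pd.DataFrame(fractions, index=samples,
                                    columns=list(config.cell_types)),
        smoker=smoker,
        cell_reference=architecture["reference"],
    )
    return MethMatrix(beta, manifest), truth


def simulate_reference_mixtures(
    reference: pd.DataFrame,
    n_samples: int,
    alpha,
    noise_sd: float = 0.02,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Beta-scale linear mixtures of reference cell profiles plus noise.

    Returns (beta probes x samples, true fractions samples x cell types);
    the direct generative model of reference-based deconvolution.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    w = rng.dirichlet(alpha, size=n_samples)
    x = reference.to_numpy() @ w.T + rng.normal(0.0, noise_sd,
                                                size=(len(reference), n_samples))
    samples = pd.Index([f"MIX{i:03d}" for i in range(n_samples)], name="sample")
    beta = pd.DataFrame(np.clip(x, 1e-6, 1 - 1e-6), index=reference.index,
                        columns=samples)
    fractions = pd.DataFrame(w, index=samples, columns=reference.columns)
    return beta, fractions


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    prs: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    family_id: pd.Series | None = None,
) -> pd.DataFrame:
    """Liability-threshold phenotypes and demographic covariates.

    liability = sqrt(h2) * PRS_std + sqrt(1 - h2) * eps; samples above the
    ``case_threshold_q`` normal quantile are cases; a ``hr_fraction`` of
    the remainder (those with highest residual liability) are labelled HR,
    giving the ordered group means CON < HR < CASE in PRS by construction.
    """
    if not 0 <= config.h2_liability <= 1:
        raise ValueError("h2_liability must lie in [0, 1]")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    samples = prs.index
    n = len(samples)
    h2 = config.h2_liability
    liab = np.sqrt(h2) * prs.to_numpy() + np.sqrt(1 - h2) * rng.standard_normal(n)
    thresh = norm.ppf(config.case_threshold_q)
    case = liab > thresh
    group = np.where(case, "CASE", "CON").astype(object)
    rest = np.where(~case)[0]
    if len(rest):
        n_hr = int(round(config.hr_fraction * len(rest)))
        hr_idx = rest[np.argsort(liab[rest])[::-1][:n_hr]]
        group[hr_idx] = "HR"
    frame = pd.DataFrame(
        {
            "group": group,
            "liability": liab,
            "case": case.astype(int),
            "age": rng.uniform(12, 30, size=n).round(1),
            "sex": rng.choice(["F", "M"], size=n),
            "tissue": rng.choice(
                ["whole_blood", "buffy_coat", "lymphoblast"], size=n,
                p=[0.5, 0.3, 0.2],
            ),
            "batch": rng.integers(1, config.n_batches + 1, size=n),
            "faces": np.clip(rng.normal(100.0, 15.0, size=n), 40, 160).round(1),
            "smoker": rng.random(n) < config.smoker_fraction,
        },
        index=samples,
    )
    frame["family_id"] = (
        family_id.reindex(samples)
        if family_id is not None
        else [f"fam{i:04d}" for i in range(n)]
    )
    return frame


# ---------------------------------------------------------------------------
# whole-study orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """One simulated sample set drawn from a shared study truth."""

    panel: SnpPanel
    meth: MethMatrix
    samples: pd.DataFrame
    prs_true: pd.Series
    truth: TrueParams


@dataclass
class SyntheticStudy:
    """Shared truth plus one or more cohorts (discovery, validation...)."""

    config: CohortConfig
    summary: pd.DataFrame
    cohorts: dict
    snp_effects: pd.Series

    def __getitem__(self, name: str) -> SyntheticCohort:
        return self.cohorts[name]


def simulate_study(
    config: CohortConfig,
    cohorts: dict | None = None,
    seed: int | None = None,
) -> SyntheticStudy:
    """Draw a shared truth and one sample set per entry of ``cohorts``.

    ``cohorts`` maps cohort name -> n_samples (default: one "discovery"
    cohort of ``config.n_samples``).  Variant metadata, causal effects,
    probe architecture and the GWAS summary are drawn once so methylation
    signatures transfer between cohorts as they would between batches of
    one study.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if cohorts is None:
        cohorts = {"discovery": config.n_samples}
    variants = _draw_variants(config, rng)
    effects = draw_snp_effects(config, variants, rng)
    architecture = _probe_architecture(config, rng)
    # summary noise uses a reference panel of the same copula for MAF only
    ref_panel, _ = simulate_genotypes(config, rng, variants=variants,
                                      n_samples=2, sample_prefix="REF")
    summary = simulate_gwas_summary(ref_panel, effects, config.gwas_n, rng,
                                    low_info_fraction=config.low_info_fraction)
    out = {}
    for name, n in cohorts.items():
        panel, truth = simulate_genotypes(
            config, rng, variants=variants, n_samples=n,
            sample_prefix=f"{name[:1].upper()}",
        )
        g = panel.dosages.to_numpy() @ effects.to_numpy()
        g_std = (g - g.mean()) / g.std() if g.std() > 0 else g * 0.0
        prs_true = pd.Series(g_std, index=panel.sample_ids, name="prs_true")
        pheno = simulate_phenotypes(prs_true, config, rng,
                                    family_id=truth.family_id)
        meth, mtruth = simulate_methylation(
            prs_true, config, rng, architecture=architecture,
            batch=pheno["batch"], smoker=pheno["smoker"],
        )
        truth.causal_snp_ids = list(effects.index[effects != 0])
        truth.snp_effects = effects
        truth.coupled_probe_ids = mtruth.coupled_probe_ids
        truth.probe_coupling = mtruth.probe_coupling
        truth.cell_fractions = mtruth.cell_fractions
        truth.smoker = mtruth.smoker
        truth.liability = pheno["liability"]
        truth.genetic_score = prs_true
        truth.cell_reference = mtruth.cell_reference
        out[name] = SyntheticCohort(panel, meth, pheno, prs_true, truth)
    return SyntheticStudy(config, summary, out, effects)
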