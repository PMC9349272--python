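"""Self-contained evaluation experiments on synthetic cohorts.

Each function runs one seeded replicate of a study-level property —
null calibration of the stratified EWAS, PMPS transfer to an independent
target set — using the same pipeline stages a real analysis would, and
returns plain-dict metrics.  Both the test suite and the acceptance
script drive these.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .methqc import beta_to_m, estimate_cell_counts, filter_probes
from .ewas import run_ewas
from .prs import filter_variants, ld_clump, mds_ancestry, score_prs
from .stratify import compute_pmps, quintile_strata, validate_glm
from .synthetic import CohortConfig, simulate_study


def _cohort_prs(cohort, summary, p_threshold=0.105):
    panel, summ, _ = filter_variants(cohort.panel, summary)
    kept = ld_clump(panel, summ)
    panel = panel.subset_variants(kept)
    res = score_prs(panel, summ, p_threshold)
    return res.scores["std"], panel


def null_calibration_run(
    seed: int,
    n_samples: int = 103,
    n_probes: int = 5000,
    bacon_iters: int = 5000,
    bacon_burnin: int = 2000,
) -> dict:
    """One replicate of the zero-coupling pipeline.

    Simulates a cohort with no PRS-methylation coupling, scores and
    stratifies the polygenic score, runs the covariate/surrogate-adjusted
    EWAS with empirical-null correction, and reports the uniformity of
    the corrected p-values (KS against U(0,1)) plus the number of
    Bonferroni-significant probes (expected: none).
    """
    cfg = CohortConfig(n_samples=n_samples, n_probes=n_probes,
                       coupling_effect=0.0, seed=seed)
    study = simulate_study(cfg)
    cohort = study["discovery"]
    prs, panel = _cohort_prs(cohort, study.summary)
    sa = quintile_strata(prs)
    ids = sa.low.union(sa.high)
    rep = filter_probes(cohort.meth, use_brain_filter=False)
    cells = estimate_cell_counts(cohort.meth, cohort.truth.cell_reference)
    mds = mds_ancestry(panel, k=4)
    samples = cohort.samples.loc[ids].copy()
    samples["stratum"] = (sa.assignments.loc[ids] == "High").astype(float)
    samples = samples.join(mds.loc[ids, ["C1", "C2"]]).join(cells.loc[ids])
    mvals = beta_to_m(cohort.meth.beta.loc[rep.retained, ids])
    ewas = run_ewas(
        mvals, samples, predictor="stratum",
        covariates=["sex", "age", "C1", "C2", "tissue",
                    *cells.columns.tolist()],
        bacon_iters=bacon_iters, bacon_burnin=bacon_burnin, seed=seed,
    )
    ks = stats.kstest(ewas.table["p_corr"].to_numpy(), "uniform")
    return {
        "n_analysed": int(len(ids)),
        "n_probes_tested": int(ewas.n_probes),
        "n_bonferroni_hits": int(ewas.table["pass_bonferroni"].sum()),
        "ks_p_uniform": float(ks.pvalue),
        "bias": float(ewas.bias),
        "inflation": float(ewas.inflation),
    }


def pmps_recovery_run(
    seed: int,
    n_discovery: int = 200,
    n_target: int = 200,
    coupling: float = 0.4,
    n_probes: int = 2000,
    p_threshold: float = 0.05,
) -> dict:
    """One replicate of the PMPS transfer experiment.

    Discovery and target cohorts are drawn from one shared truth at the
    given PRS-methylation coupling; the discovery quintile-stratified EWAS
    supplies PMPS weights, scored in the target.  Reports the target-set
    PMPS~PRS correlation and the p-value of the High-vs-Low stratum GLM
    on target PMPS.
    """
    cfg = CohortConfig(n_samples=n_discovery, n_probes=n_probes,
                       coupling_effect=coupling, seed=seed)
    study = simulate_study(cfg, cohorts={"discovery": n_discovery,
                                         "target": n_target})
    disc = study["discovery"]
    targ = study["target"]
    prs_d, _ = _cohort_prs(disc, study.summary)
    prs_t, _ = _cohort_prs(targ, study.summary)
    sa = quintile_strata(prs_d)
    ids = sa.low.union(sa.high)
    rep = filter_probes(disc.meth, use_brain_filter=False)
    samples = disc.samples.loc[ids].copy()
    samples["stratum"] = (sa.assignments.loc[ids] == "High").astype(float)
    mvals = beta_to_m(disc.meth.beta.loc[rep.retained, ids])
    ewas = run_ewas(mvals, samples, predictor="stratum",
                    covariates=["sex", "age"], bacon=False, seed=seed)
    trep = filter_probes(targ.meth, use_brain_filter=False)
    target = targ.meth.subset_probes(
        trep.retained.intersection(ewas.table.index))
    pmps = compute_pmps(target, ewas, p_threshold=p_threshold)
    r = float(np.corrcoef(pmps.scores.loc[prs_t.index], prs_t)[0, 1])
    tsa = quintile_strata(prs_t)
    tids = tsa.low.union(tsa.high)
    data = targ.samples.loc[tids].copy()
    data["stratum"] = np.where(tsa.assignments.loc[tids] == "High",
                               "High", "Low")
    data["pmps"] = pmps.scores.loc[tids]
    glm = validate_glm(data, group="stratum", covariates=["age", "sex"])
    return {
        "n_cpgs": int(pmps.n_cpgs),
        "pmps_prs_r": r,
        "stratum_p": float(glm.terms.loc["stratum", "p"]),
        "stratum_eta2p": float(glm.terms.loc["stratum", "eta2p"]),
    }


def deconvolution_error_run(seed: int, n_samples: int = 50,
                            noise_sd: float = 0.02) -> dict:
    """Mean absolute cell-fraction error on beta-scale reference mixtures."""
    from .synthetic import (DEFAULT_DIRICHLET_ALPHA, _probe_architecture,
                            simulate_reference_mixtures)

    rng = np.random.default_rng(seed)
    cfg = CohortConfig(n_probes=300, n_coupled_probes=10, seed=seed)
    arch = _probe_architecture(cfg, rng)
    reference = arch["reference"]
    beta, truth = simulate_reference_mixtures(
        reference, n_samples=n_samples, alpha=DEFAULT_DIRICHLET_ALPHA,
        noise_sd=noise_sd, seed=seed + 1,
    )
    est = estimate_cell_counts(beta, reference)
    mae = float((est - truth).abs().to_numpy().mean())
    return {"mae": mae, "n_samples": n_samples, "noise_sd": noise_sd}
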