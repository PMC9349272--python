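"""Variant QC, clumping, scoring, threshold optimization, relatedness and
ancestry checks, including brute-force oracles for the greedy clump."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_panel, make_summary
from stratmeth.prs import (
    filter_variants,
    ibs_nn_outliers,
    ld_clump,
    mds_ancestry,
    nagelkerke_r2,
    optimize_threshold,
    relatedness_filter,
    score_prs,
)
from stratmeth.synthetic import CohortConfig, simulate_genotypes


# --- filter_variants --------------------------------------------------------

def test_strand_ambiguous_variants_removed():
    panel = make_panel(np.ones((4, 3)), a1=["A", "A", "C"], a2=["T", "G", "G"])
    summary = make_summary(panel, beta=[0.1] * 3, p=[0.5] * 3)
    out, _, log = filter_variants(panel, summary)
    assert list(out.variants.index) == ["snp1"]
    reasons = dict(zip(log["snp"], log["reason"]))
    assert reasons["snp0"] == "strand_ambiguous"
    assert reasons["snp2"] == "strand_ambiguous"


def test_maf_boundary_inclusive():
    panel = make_panel(np.ones((4, 2)), maf=[0.04, 0.05])
    summary = make_summary(panel, beta=[0.1, 0.1], p=[0.5, 0.5])
    out, _, _ = filter_variants(panel, summary)
    assert list(out.variants.index) == ["snp1"]


def test_info_boundary_inclusive():
    panel = make_panel(np.ones((4, 2)), maf=[0.2, 0.2], info=[0.79, 0.8])
    summary = make_summary(panel, beta=[0.1, 0.1], p=[0.5, 0.5])
    out, _, _ = filter_variants(panel, summary)
    assert list(out.variants.index) == ["snp1"]


def test_swapped_panel_coding_flips_dosage_and_preserves_prs():
    # the same genotypes coded on the other allele must align back to the
    # summary's effect allele (dosage -> 2 - d) and give identical scores
    rng = np.random.default_rng(5)
    d = rng.integers(0, 3, size=(30, 4)).astype(float)
    panel = make_panel(d, maf=[0.3] * 4, a1=["A", "C", "A", "G"],
                      a2=["G", "T", "C", "T"])
    summary = make_summary(panel, beta=[0.2, -0.1, 0.3, 0.15], p=[0.01] * 4)
    recoded = make_panel(2 - d, maf=[0.3] * 4, a1=["G", "T", "C", "T"],
                         a2=["A", "C", "A", "G"])
    p_ref, s_ref, _ = filter_variants(panel, summary)
    p_swp, s_swp, _ = filter_variants(recoded, summary)
    assert np.allclose(p_swp.dosages.to_numpy(), panel.dosages.to_numpy())
    ref = score_prs(p_ref, s_ref, 1.1).scores["raw"]
    swp = score_prs(p_swp, s_swp, 1.1).scores["raw"]
    assert np.allclose(ref.to_numpy(), swp.to_numpy(), atol=1e-12)


def test_unresolvable_mismatch_dropped_not_raised():
    panel = make_panel(np.ones((4, 2)), a1=["A", "A"], a2=["C", "C"])
    summary = make_summary(panel, beta=[0.1, 0.1], p=[0.5] * 2,
                           a1=["A", "A"], a2=["C", "G"])
    out, _, log = filter_variants(panel, summary)
    assert list(out.variants.index) == ["snp0"]
    assert (log["reason"] == "allele_mismatch").sum() == 1


def test_allele_relabel_leaves_standardized_prs_invariant():
    # relabel A1<->A2: dosage -> 2 - d and effect -> -effect shifts the raw
    # score by a constant, so the standardized score is unchanged
    rng = np.random.default_rng(6)
    d = rng.integers(0, 3, size=(40, 5)).astype(float)
    panel = make_panel(d, maf=[0.25] * 5)
    beta = rng.normal(0, 0.2, 5)
    summary = make_summary(panel, beta=beta, p=[0.01] * 5)
    relabelled = make_panel(2 - d, maf=[0.25] * 5, a1=["G"] * 5, a2=["A"] * 5)
    summary_rel = make_summary(relabelled, beta=-beta, p=[0.01] * 5,
                               a1=["G"] * 5, a2=["A"] * 5)
    a = score_prs(panel, summary, 1.1).scores["std"]
    b = score_prs(relabelled, summary_rel, 1.1).scores["std"]
    assert np.allclose(a, b, atol=1e-12)


# --- ld_clump ---------------------------------------------------------------

def _brute_force_clump(panel, summary, window_kb=250.0, r2_max=0.1):
    """Independent greedy oracle: explicit loop over p-sorted variants."""
    v = panel.variants
    order = sorted(v.index, key=lambda s: (summary.at[s, "p"],
                                           v.at[s, "chrom"], v.at[s, "pos"]))
    removed, kept = set(), []
    for sid in order:
        if sid in removed:
            continue
        kept.append(sid)
        for other in v.index:
            if other in removed or other in kept:
                continue
            if v.at[other, "chrom"] != v.at[sid, "chrom"]:
                continue
            if abs(v.at[other, "pos"] - v.at[sid, "pos"]) > window_kb * 1000:
                continue
            x = panel.dosages[sid].to_numpy()
            y = panel.dosages[other].to_numpy()
            if x.std() == 0 or y.std() == 0:
                continue
            if np.corrcoef(x, y)[0, 1] ** 2 > r2_max:
                removed.add(other)
    return set(kept)


def test_clump_keeps_only_best_of_correlated_trio():
    base = np.random.default_rng(0).integers(0, 3, size=(50, 1)).astype(float)
    d = np.hstack([base, base, base])  # r2 = 1 pairwise
    panel = make_panel(d, pos=[1000, 2000, 3000])
    summary = make_summary(panel, beta=[0.1] * 3, p=[1e-8, 1e-4, 1e-2])
    assert ld_clump(panel, summary) == ["snp0"]


def test_clump_retains_all_independent_snps():
    rng = np.random.default_rng(1)
    d = rng.integers(0, 3, size=(200, 5)).astype(float)
    panel = make_panel(d)
    summary = make_summary(panel, beta=[0.1] * 5,
                           p=[0.5, 0.1, 0.2, 0.3, 0.4])
    kept = ld_clump(panel, summary, r2_max=0.2)
    assert kept == list(panel.variants.index)


@pytest.mark.parametrize("order", [(0, 1), (1, 0)])
def test_clump_tie_broken_by_position(order):
    base = np.random.default_rng(2).integers(0, 3, size=(50, 1)).astype(float)
    d = np.hstack([base, base])
    pos = [2000, 1000] if order == (1, 0) else [1000, 2000]
    panel = make_panel(d, pos=pos)
    summary = make_summary(panel, beta=[0.1, 0.1], p=[1e-3, 1e-3])
    kept = ld_clump(panel, summary)
    assert len(kept) == 1
    assert panel.variants.at[kept[0], "pos"] == 1000


def test_clump_matches_brute_force_on_random_panels():
    rng = np.random.default_rng(3)
    for trial in range(8):
        n_snps = int(rng.integers(4, 11))
        base = rng.integers(0, 3, size=(60, n_snps)).astype(float)
        # inject correlated pairs
        for j in range(1, n_snps, 2):
            if rng.random() < 0.6:
                base[:, j] = base[:, j - 1]
        pos = np.sort(rng.choice(np.arange(1, 500) * 1000, n_snps,
                                 replace=False))
        panel = make_panel(base, pos=pos)
        summary = make_summary(panel, beta=rng.normal(0, 0.1, n_snps),
                               p=rng.uniform(1e-8, 1, n_snps))
        got = set(ld_clump(panel, summary))
        assert got == _brute_force_clump(panel, summary)


def test_clumped_set_has_no_residual_ld():
    cfg = CohortConfig(n_samples=150, n_snps=60, n_blocks=6, block_rho=0.9,
                      n_causal_snps=5, seed=31)
    panel, _ = simulate_genotypes(cfg)
    summary = make_summary(panel, beta=np.zeros(60),
                           p=np.random.default_rng(4).uniform(0, 1, 60))
    kept = ld_clump(panel, summary, window_kb=250, r2_max=0.1)
    v = panel.variants
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            if v.at[a, "chrom"] != v.at[b, "chrom"]:
                continue
            if abs(v.at[a, "pos"] - v.at[b, "pos"]) > 250_000:
                continue
            r2 = np.corrcoef(panel.dosages[a], panel.dosages[b])[0, 1] ** 2
            assert r2 <= 0.1 + 1e-12


def test_empty_panel_rejected():
    panel = make_panel(np.ones((4, 1)))
    empty = panel.subset_variants([])
    with pytest.raises(ValueError):
        ld_clump(empty, make_summary(panel, beta=[0.1], p=[0.5]))


# --- score_prs --------------------------------------------------------------

def test_single_snp_average_convention():
    panel = make_panel(np.array([[2.0]]))
    summary = make_summary(panel, beta=[0.5], p=[0.01])
    res = score_prs(panel, summary, 0.05)
    # (0.5 * 2) / (2 * 1) = 0.5
    assert res.scores["raw"].iloc[0] == pytest.approx(0.5)
    assert res.n_snps_included == 1


def test_zero_effects_zero_scores():
    panel = make_panel(np.random.default_rng(0).integers(0, 3, (10, 3)))
    summary = make_summary(panel, beta=[0.0] * 3, p=[0.01] * 3)
    res = score_prs(panel, summary, 0.05)
    assert np.allclose(res.scores["raw"], 0.0)


def test_score_difference_closed_form():
    d = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 1.0]])
    panel = make_panel(d)
    b = 0.3
    summary = make_summary(panel, beta=[0.1, 0.2, b], p=[0.01] * 3)
    res = score_prs(panel, summary, 0.05)
    diff = res.scores["raw"].iloc[1] - res.scores["raw"].iloc[0]
    assert diff == pytest.approx(b / (2 * 3))


def test_missing_dosage_imputed_as_twice_maf():
    d = np.array([[np.nan], [2.0]])
    panel = make_panel(d, maf=[0.25])
    summary = make_summary(panel, beta=[1.0], p=[0.01])
    res = score_prs(panel, summary, 0.05)
    assert res.scores["raw"].iloc[0] == pytest.approx(2 * 0.25 / 2)


def test_no_snps_past_threshold_errors():
    panel = make_panel(np.ones((3, 1)))
    summary = make_summary(panel, beta=[0.1], p=[0.5])
    with pytest.raises(ValueError, match="1e-08"):
        score_prs(panel, summary, 1e-8)


def test_reference_standardization():
    panel = make_panel(np.random.default_rng(7).integers(0, 3, (50, 4)))
    summary = make_summary(panel, beta=[0.1, -0.2, 0.3, 0.2], p=[0.01] * 4)
    res = score_prs(panel, summary, 0.05)
    assert res.scores["std"].mean() == pytest.approx(0.0, abs=1e-12)
    assert res.scores["std"].std(ddof=0) == pytest.approx(1.0)
    # external reference mean/SD honoured
    res2 = score_prs(panel, summary, 0.05, ref_mean=0.0, ref_sd=1.0)
    assert np.allclose(res2.scores["std"], res2.scores["raw"])


# --- optimize_threshold -----------------------------------------------------

def test_nagelkerke_zero_when_likelihood_unchanged():
    assert nagelkerke_r2(-50.0, -50.0, 100) == pytest.approx(0.0)


def test_nagelkerke_null_phenotype_near_zero():
    rng = np.random.default_rng(8)
    d = rng.integers(0, 3, size=(1000, 20)).astype(float)
    panel = make_panel(d, maf=[0.3] * 20)
    summary = make_summary(panel, beta=rng.normal(0, 0.1, 20),
                           p=rng.uniform(0, 0.04, 20))
    pheno = pd.Series(rng.integers(0, 2, 1000).astype(float),
                      index=panel.sample_ids)
    best, profile = optimize_threshold(panel, summary, pheno,
                                       grid=(0.05, 0.5))
    assert profile["r2"].max() < 0.01


def test_threshold_recovery_on_heritable_phenotype():
    # phenotype built from the true effects: informative thresholds win
    rng = np.random.default_rng(9)
    cfg = CohortConfig(n_samples=400, n_snps=200, n_blocks=20,
                      n_causal_snps=30, effect_sd=0.3, seed=41)
    panel, _ = simulate_genotypes(cfg)
    from stratmeth.synthetic import draw_snp_effects, simulate_gwas_summary

    effects = draw_snp_effects(cfg, panel.variants.assign(block=0), rng)
    summary = simulate_gwas_summary(panel, effects, 100_000, seed=42)
    g = panel.dosages.to_numpy() @ effects.to_numpy()
    liab = (g - g.mean()) / g.std() + 0.5 * rng.standard_normal(400)
    pheno = pd.Series((liab > np.quantile(liab, 0.6)).astype(float),
                      index=panel.sample_ids)
    best, profile = optimize_threshold(panel, summary, pheno)
    assert profile["r2"].max() > 0.05
    # HR-style missing phenotypes are simply excluded
    pheno_missing = pheno.copy()
    pheno_missing.iloc[:50] = np.nan
    best2, _ = optimize_threshold(panel, summary, pheno_missing)
    assert np.isfinite(best2)


# --- relatedness ------------------------------------------------------------

def test_duplicate_sample_has_pi_hat_one():
    cfg = CohortConfig(n_samples=20, n_snps=500, n_blocks=50, block_rho=0.0,
                      n_causal_snps=5, maf_range=(0.2, 0.5), seed=51)
    panel, _ = simulate_genotypes(cfg)
    dup = panel.dosages.copy()
    dup.loc["S0001"] = dup.loc["S0000"]
    panel_dup = make_panel(dup.to_numpy(), maf=panel.variants["maf"].to_numpy(),
                           sample_ids=list(dup.index))
    rep = relatedness_filter(panel_dup)
    pair = rep.pairs[(rep.pairs["id1"] == "S0000")
                     & (rep.pairs["id2"] == "S0001")]
    assert pair["pi_hat"].iloc[0] > 0.95
    assert "S0001" in rep.exclusions  # tie on missingness: later id dropped


def test_unrelated_samples_not_excluded():
    cfg = CohortConfig(n_samples=20, n_snps=2000, n_blocks=200, block_rho=0.0,
                      n_causal_snps=5, maf_range=(0.2, 0.5), seed=53)
    panel, _ = simulate_genotypes(cfg)
    rep = relatedness_filter(panel)
    assert rep.pairs["pi_hat"].mean() < 0.03
    assert rep.exclusions == []


def test_monomorphic_panel_rejected():
    panel = make_panel(np.zeros((5, 3)), maf=[0.0] * 3)
    with pytest.raises(ValueError, match="monomorphic"):
        relatedness_filter(panel)


# --- MDS ancestry -----------------------------------------------------------

def test_mds_separates_divergent_subpopulations():
    rng = np.random.default_rng(10)
    m = 300
    maf_a = rng.uniform(0.1, 0.3, m)
    maf_b = np.clip(maf_a + 0.35, 0.0, 0.9)
    da = rng.binomial(2, maf_a, size=(50, m)).astype(float)
    db = rng.binomial(2, maf_b, size=(50, m)).astype(float)
    panel = make_panel(np.vstack([da, db]), maf=np.full(m, 0.25))
    comps = mds_ancestry(panel, k=2)
    label = np.r_[np.zeros(50), np.ones(50)]
    r = np.corrcoef(comps["C1"], label)[0, 1]
    assert abs(r) > 0.9
    assert abs(comps.mean()).max() < 1e-10


def test_mds_homogeneous_cohort_uninformative():
    cfg = CohortConfig(n_samples=200, n_snps=500, n_blocks=50, block_rho=0.0,
                      n_causal_snps=5, maf_range=(0.2, 0.5), seed=55)
    panel, _ = simulate_genotypes(cfg)
    comps = mds_ancestry(panel, k=2)
    label = np.r_[np.zeros(100), np.ones(100)]  # arbitrary split
    for c in comps.columns:
        assert abs(np.corrcoef(comps[c], label)[0, 1]) < 0.2


def test_mds_k_bounds():
    panel = make_panel(np.random.default_rng(0).integers(0, 3, (5, 10)))
    with pytest.raises(ValueError):
        mds_ancestry(panel, k=5)


# --- IBS nearest-neighbour outliers ----------------------------------------

def test_homogeneous_cohort_has_no_nn_outliers():
    cfg = CohortConfig(n_samples=100, n_snps=600, n_blocks=60, block_rho=0.0,
                      n_causal_snps=5, maf_range=(0.2, 0.5), seed=57)
    panel, _ = simulate_genotypes(cfg)
    rep = ibs_nn_outliers(panel)
    assert rep.exclusions == []
    assert (rep.stats["z"].abs() < 4).all()


def test_planted_outlier_is_unique_exclusion():
    rng = np.random.default_rng(11)
    m = 600
    maf = rng.uniform(0.1, 0.4, m)
    d = rng.binomial(2, maf, size=(60, m)).astype(float)
    # one sample from a divergent frequency spectrum
    d[0] = rng.binomial(2, np.clip(1 - maf, 0.05, 0.95), size=m)
    panel = make_panel(d, maf=np.full(m, 0.25))
    rep = ibs_nn_outliers(panel)
    assert rep.exclusions == ["s0"]


def test_nn_degenerate_neighbour_count():
    rng = np.random.default_rng(12)
    d = rng.integers(0, 3, size=(8, 50)).astype(float)
    panel = make_panel(d)
    rep = ibs_nn_outliers(panel, n_neighbours=100)
    from stratmeth.prs import ibs_distance_matrix

    dist = ibs_distance_matrix(panel).to_numpy()
    expected = (dist.sum(axis=1)) / 7  # mean over all others (diag is 0)
    assert np.allclose(rep.stats["mean_nn_dist"], expected)


def test_nn_requires_enough_samples():
    panel = make_panel(np.ones((5, 10)))
    with pytest.raises(ValueError):
        ibs_nn_outliers(panel)
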