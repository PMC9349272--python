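"""EWAS core: surrogate-variable estimation, per-probe linear models on
M-values, empirical-null bias/inflation correction, and multiple-testing
thresholds.

The per-probe model regresses M-values on a binary polygenic-score
stratum (Low = 0, High = 1) plus covariates; residual variances are
optionally moderated by an empirical-Bayes scaled-inverse-chi-square
prior.  Test statistics are then rescaled by an empirical null: a
three-component Gaussian mixture fitted by Gibbs sampling whose null
component mean is the bias and SD the inflation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import EwasTable


# ---------------------------------------------------------------------------
# design utilities
# ---------------------------------------------------------------------------

def build_design(
    samples: pd.DataFrame,
    predictor: str,
    covariates=(),
    surrogate: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble a full-rank design matrix with an intercept.

    Categorical covariates are expanded to treatment-coded dummies;
    the predictor column is kept first after the intercept so per-probe
    fits report its coefficient.
    """
    cols = {"const": pd.Series(1.0, index=samples.index)}
    cols[predictor] = samples[predictor].astype(float)
    for cov in covariates:
        s = samples[cov]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
        else:
            cols[cov] = s.astype(float)
    x = pd.DataFrame(cols)
    if surrogate is not None:
        for c in surrogate.columns:
            x[c] = surrogate[c].astype(float)
    _check_full_rank(x)
    return x


def _check_full_rank(x: pd.DataFrame) -> None:
    arr = x.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns via QR pivoting
        _, r = np.linalg.qr(arr)
        bad = [x.columns[i] for i in range(arr.shape[1])
               if abs(r[i, i]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"design matrix is collinear; offending columns: {bad}")


# ---------------------------------------------------------------------------
# surrogate variables (two-step residual SVD + Buja-Eyuboglu selection)
# ---------------------------------------------------------------------------

def estimate_surrogates(
    m_matrix: pd.DataFrame,
    design: pd.DataFrame,
    n_perm: int = 20,
    alpha: float = 0.05,
    max_sv: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Surrogate variables from the residual SVD, with the number of
    components chosen by Buja-Eyuboglu permutation.

    M-values (probes x samples) are residualized on the fixed design; the
    left singular vectors of the residual matrix (samples dimension) are
    candidate surrogates.  Each leading eigenvalue share is compared to
    its null distribution over ``n_perm`` within-probe permutations of the
    residuals; components are kept sequentially while the permutation
    p-value is below ``alpha``.  May return zero columns.
    """
    rng = np.random.default_rng(seed)
    x = design.to_numpy(dtype=float)
    y = m_matrix.to_numpy(dtype=float).T  # samples x probes
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    svals = np.linalg.svd(resid, compute_uv=False)
    shares = svals**2 / np.sum(svals**2)
    kmax = min(max_sv, len(shares))
    exceed = np.zeros(kmax)
    for _ in range(n_perm):
        perm = resid.copy()
        # permute each probe's residuals independently (row-wise exchange)
        for j in range(perm.shape[1]):
            rng.shuffle(perm[:, j])
        ps = np.linalg.svd(perm, compute_uv=False)
        pshares = ps**2 / np.sum(ps**2)
        exceed += pshares[:kmax] >= shares[:kmax]
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    k = 0
    for j in range(kmax):
        if pvals[j] < alpha:
            k += 1
        else:
            break
    u, _, _ = np.linalg.svd(resid, full_matrices=False)
    sv = pd.DataFrame(u[:, :k], index=m_matrix.columns,
                      columns=[f"SV{i + 1}" for i in range(k)])
    sv.attrs["perm_pvalues"] = pvals
    return sv


# ---------------------------------------------------------------------------
# per-probe linear model with optional variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (limma-style)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes moderation of residual variances.

    Method-of-moments fit of a scaled inverse-chi-square prior to the
    observed variances (matching the standard moderated-t machinery):
    returns (posterior variances, prior df d0, prior variance s0^2);
    d0 may be inf when the variances are essentially exchangeable.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
        post = np.full_like(s2, s0_2)
    return post, float(d0), float(s0_2)


def fit_probe_lm(
    m_matrix: pd.DataFrame,
    design: pd.DataFrame,
    coef: str | None = None,
    moderate_var: bool = True,
    min_n: int = 20,
) -> pd.DataFrame:
    """Per-probe OLS of M-values on the design; returns coef/SE/t/p.

    ``coef`` names the design column of interest (default: the first
    non-intercept column).  With ``moderate_var`` the residual variances
    are shrunk toward an empirical-Bayes prior and the t reference gains
    the prior degrees of freedom.  Probes with missing values are fit
    complete-case, requiring at least ``min_n`` samples.
    """
    if coef is None:
        coef = next(c for c in design.columns if c != "const")
    design = design.loc[m_matrix.columns]
    _check_full_rank(design)
    x = design.to_numpy(dtype=float)
    y = m_matrix.to_numpy(dtype=float).T  # samples x probes
    n, q = x.shape
    if n <= q + 5:
        raise ValueError("need n_samples > n_design_columns + 5")
    j = design.columns.get_loc(coef)
    xtx_inv = np.linalg.inv(x.T @ x)
    complete = ~np.isnan(y).any(axis=0)
    betas = np.full(y.shape[1], np.nan)
    s2 = np.full(y.shape[1], np.nan)
    dfs = np.full(y.shape[1], float(n - q))
    if complete.any():
        yc = y[:, complete]
        b = xtx_inv @ (x.T @ yc)
        resid = yc - x @ b
        betas[complete] = b[j]
        s2[complete] = (resid**2).sum(axis=0) / (n - q)
    for idx in np.where(~complete)[0]:
        mask = ~np.isnan(y[:, idx])
        if mask.sum() < max(min_n, q + 2):
            continue
        xm, ym = x[mask], y[mask, idx]
        xtxm = np.linalg.inv(xm.T @ xm)
        bm = xtxm @ (xm.T @ ym)
        rm = ym - xm @ bm
        betas[idx] = bm[j]
        s2[idx] = (rm**2).sum() / (mask.sum() - q)
        dfs[idx] = mask.sum() - q
        # per-probe design inverse differs; fold into s2 via the ratio
        s2[idx] *= xtxm[j, j] / xtx_inv[j, j]
    ok = ~np.isnan(s2)
    df_total = dfs.copy()
    if moderate_var:
        post, d0, _ = squeeze_var(s2[ok], float(np.median(dfs[ok])))
        s2_used = s2.copy()
        s2_used[ok] = post
        df_total[ok] = dfs[ok] + (d0 if np.isfinite(d0) else 1e6)
    else:
        s2_used = s2
    se = np.sqrt(s2_used * xtx_inv[j, j])
    t = betas / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {"coef": betas, "se": se, "t": t, "p": p, "df": df_total},
        index=m_matrix.index,
    )
    return out.dropna(subset=["coef"])


# ---------------------------------------------------------------------------
# empirical-null (bias/inflation) correction by Gibbs sampling
# ---------------------------------------------------------------------------

@dataclass
class BaconFit:
    """Posterior summary of the three-component Gaussian mixture.

    Component 0 is the empirical null: its mean is the bias and SD the
    inflation applied as corrected z = (z - bias) / inflation.
    """

    bias: float
    inflation: float
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    niter: int
    burnin: int
    seed: int
    traces: dict = field(default_factory=dict)


def _trunc_normal(rng, loc, scale, lower, upper):
    """One draw from N(loc, scale^2) truncated to (lower, upper), by
    inverse-CDF in the upper/lower tail as appropriate."""
    if not np.isfinite(lower) and not np.isfinite(upper):
        return rng.normal(loc, scale)
    a = -np.inf if not np.isfinite(lower) else (lower - loc) / scale
    b = np.inf if not np.isfinite(upper) else (upper - loc) / scale
    lo = stats.norm.cdf(a) if np.isfinite(a) else 0.0
    hi = stats.norm.cdf(b) if np.isfinite(b) else 1.0
    if hi - lo < 1e-12:  # truncation region far in a tail: pin to boundary
        return lower if np.isfinite(lower) else upper
    u = rng.uniform(lo, hi)
    return loc + scale * stats.norm.ppf(u)


def bacon_correct(
    z_scores,
    niter: int = 5000,
    burnin: int = 2000,
    seed: int = 0,
    prior_weights: tuple = (5.0, 1.0, 1.0),
    prior_mean_loc: tuple = (0.0, 4.0, -4.0),
    prior_mean_n: tuple = (1.0, 1.0, 1.0),
    prior_sd_shape: float = 2.0,
    prior_sd_scale: float = 1.0,
    alt_separation: float = 3.0,
) -> tuple[BaconFit, np.ndarray, np.ndarray]:
    """Estimate empirical-null bias and inflation from a vector of z-scores.

    Fits pi0 N(mu0, s0^2) + pi1 N(mu1, s1^2) + pi2 N(mu2, s2^2) by Gibbs
    sampling with conjugate updates: Dirichlet prior on the weights
    (null-dominant), normal priors on means (alternatives anchored at
    +/-4), inverse-gamma priors on variances.  The empirical null is
    identified as the central component: alternative means are sampled
    from normals truncated to the null's tails (beyond mu0 +/-
    ``alt_separation`` * s0), and components are relabelled each sweep so
    the null has the smallest |mean|.  Without the truncation the mixture
    is only weakly identified and the alternatives absorb the null's
    tails, biasing the inflation estimate downward.  Posterior means of
    (mu0, s0) over the post-burn-in sweeps give (bias, inflation);
    returns (fit, corrected z, corrected two-sided p).
    """
    z = np.asarray(z_scores, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z-scores present")
    m = len(z)
    if m < 1000:
        warnings.warn(f"only {m} z-scores; empirical-null estimates may be unstable")
    rng = np.random.default_rng(seed)
    gamma = np.asarray(prior_weights, float)
    lam = np.asarray(prior_mean_loc, float)
    tau = np.asarray(prior_mean_n, float)
    a0, b0 = prior_sd_shape, prior_sd_scale

    med = np.median(z)
    mad = 1.4826 * np.median(np.abs(z - med))
    mad = mad if mad > 0 else max(z.std(), 1e-3)
    mu = np.array([med, med + 3 * mad, med - 3 * mad])
    sig2 = np.array([mad**2, mad**2, mad**2])
    pi = np.array([0.9, 0.05, 0.05])

    keep = niter - burnin
    tr_mu0 = np.empty(keep)
    tr_s0 = np.empty(keep)
    tr_pi = np.empty((keep, 3))
    tr_mu = np.empty((keep, 3))
    tr_sd = np.empty((keep, 3))
    u_buf = np.empty(m)
    for it in range(niter):
        # component assignments
        logp = (
            np.log(pi)[None, :]
            - 0.5 * np.log(2 * np.pi * sig2)[None, :]
            - 0.5 * (z[:, None] - mu[None, :]) ** 2 / sig2[None, :]
        )
        logp -= logp.max(axis=1, keepdims=True)
        prob = np.exp(logp)
        prob /= prob.sum(axis=1, keepdims=True)
        rng.random(out=u_buf)
        c = (u_buf[:, None] > np.cumsum(prob, axis=1)).sum(axis=1)
        counts = np.bincount(c, minlength=3).astype(float)
        # weights
        pi = rng.dirichlet(gamma + counts)
        # means and variances per component (semi-conjugate); alternative
        # means truncated to the null's tails for identifiability
        s0 = np.sqrt(sig2[0])
        bounds = [(-np.inf, np.inf),
                  (mu[0] + alt_separation * s0, np.inf),
                  (-np.inf, mu[0] - alt_separation * s0)]
        for comp in range(3):
            mask = c == comp
            nzc = counts[comp]
            zsum = z[mask].sum() if nzc else 0.0
            post_prec = tau[comp] + nzc
            post_mean = (tau[comp] * lam[comp] + zsum) / post_prec
            post_sd = np.sqrt(sig2[comp] / post_prec)
            mu[comp] = _trunc_normal(rng, post_mean, post_sd, *bounds[comp])
            sse = ((z[mask] - mu[comp]) ** 2).sum() if nzc else 0.0
            sig2[comp] = 1.0 / rng.gamma(a0 + nzc / 2.0, 1.0 / (b0 + sse / 2.0))
        # identify the null as the component with smallest |mean|
        null = int(np.argmin(np.abs(mu)))
        if null != 0:
            order = [null] + [j for j in range(3) if j != null]
            mu, sig2, pi = mu[order], sig2[order], pi[order]
        if it >= burnin:
            k = it - burnin
            tr_mu0[k] = mu[0]
            tr_s0[k] = np.sqrt(sig2[0])
            tr_pi[k] = pi
            tr_mu[k] = mu
            tr_sd[k] = np.sqrt(sig2)
    bias = float(tr_mu0.mean())
    inflation = float(tr_s0.mean())
    fit = BaconFit(
        bias=bias,
        inflation=inflation,
        weights=tr_pi.mean(axis=0),
        means=tr_mu.mean(axis=0),
        sds=tr_sd.mean(axis=0),
        niter=niter,
        burnin=burnin,
        seed=seed,
        traces={"mu0_sd": float(tr_mu0.std()), "s0_sd": float(tr_s0.std())},
    )
    z_corr = (z - bias) / inflation
    p_corr = np.clip(2.0 * stats.norm.sf(np.abs(z_corr)), np.finfo(float).tiny, 1.0)
    return fit, z_corr, p_corr


def z_from_p(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Signed z-scores from two-sided p and coefficient sign:
    z = sign(b) * Phi^-1(1 - p/2)."""
    z = stats.norm.isf(np.asarray(p, float) / 2.0)
    return np.sign(np.asarray(sign, float)) * z


# ---------------------------------------------------------------------------
# thresholds, FDR, plotting tables
# ---------------------------------------------------------------------------

class BonferroniThreshold(NamedTuple):
    value: float
    value_3sf: float


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> BonferroniThreshold:
    """alpha/m, with the value rounded to 3 significant figures alongside
    full precision."""
    if m <= 0:
        raise ValueError("m must be positive")
    value = alpha / m
    exponent = np.floor(np.log10(abs(value)))
    rounded = round(value, int(2 - exponent))
    return BonferroniThreshold(value, float(rounded))


def bh_fdr(p_vector) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-adjusted)."""
    p = np.asarray(p_vector, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def qq_manhattan_data(
    table: pd.DataFrame,
    p_col: str = "p_corr",
    threshold: float | None = None,
    inflection: float = 0.002,
) -> dict:
    """Plot-ready tables: expected vs observed -log10 p, and chr/pos/-log10 p.

    Expected quantiles use the rank-0.5 convention:
    -log10((rank - 0.5)/m) for ranks 1..m of ascending p.
    """
    p = table[p_col].to_numpy(dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame(
        {
            "expected": expected,
            "observed": -np.log10(p[order]),
        },
        index=table.index[order],
    )
    man = None
    if {"chrom", "pos"}.issubset(table.columns):
        man = pd.DataFrame(
            {
                "chrom": table["chrom"],
                "pos": table["pos"],
                "mlog10p": -np.log10(p),
            },
            index=table.index,
        )
    return {
        "qq": qq,
        "manhattan": man,
        "threshold": threshold,
        "inflection": inflection,
    }


# ---------------------------------------------------------------------------
# orchestrated EWAS
# ---------------------------------------------------------------------------

def run_ewas(
    m_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    predictor: str = "stratum",
    covariates=(),
    n_sv: int | str = "auto",
    moderate_var: bool = True,
    bacon: bool = True,
    bacon_iters: int = 5000,
    bacon_burnin: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    manifest: pd.DataFrame | None = None,
) -> EwasTable:
    """Full EWAS stage: surrogate variables, per-probe fits, empirical-null
    correction, BH FDR, and the Bonferroni threshold for the tested set."""
    design0 = build_design(samples, predictor, covariates)
    if n_sv == "auto":
        sv = estimate_surrogates(m_matrix, design0, seed=seed)
    elif int(n_sv) > 0:
        sv = estimate_surrogates(m_matrix, design0, alpha=1.1,
                                 max_sv=int(n_sv), seed=seed)
        sv = sv.iloc[:, : int(n_sv)]
    else:
        sv = pd.DataFrame(index=m_matrix.columns)
    design = build_design(samples, predictor, covariates,
                          surrogate=sv if sv.shape[1] else None)
    fits = fit_probe_lm(m_matrix, design, coef=predictor,
                        moderate_var=moderate_var)
    z = z_from_p(fits["p"].to_numpy(), fits["coef"].to_numpy())
    if bacon:
        fit, z_corr, p_corr = bacon_correct(z, niter=bacon_iters,
                                            burnin=bacon_burnin, seed=seed)
        bias, inflation = fit.bias, fit.inflation
    else:
        bias, inflation = 0.0, 1.0
        z_corr, p_corr = z, np.clip(2.0 * stats.norm.sf(np.abs(z)),
                                    np.finfo(float).tiny, 1.0)
    table = fits.copy()
    table["z"] = z
    table["z_corr"] = z_corr
    table["p_corr"] = p_corr
    table["q"] = bh_fdr(p_corr)
    thresh = bonferroni_threshold(alpha, len(table))
    table["pass_bonferroni"] = table["p_corr"] < thresh.value
    if manifest is not None:
        table = table.join(manifest[["chrom", "pos", "gene"]], how="left")
    return EwasTable(
        table=table,
        bias=bias,
        inflation=inflation,
        bonferroni=thresh.value,
        n_sv=sv.shape[1],
        extras={"bonferroni_3sf": thresh.value_3sf},
    )
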