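"""Probe-level filtering, beta/M transforms, reference-based cell-type
deconvolution and epigenetic smoking inference.

The analysis probe set is the intersection of four filters applied in a
fixed reporting order: data variability (10th-90th percentile beta range
> 0.05), membership of a blood-variable reference list, blood-brain
correlation (|mean r| >= 0.3, optional), and absence of an annotated
probe SNP within 50 bp.  Being a pure intersection, the retained set is
invariant to filter order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .containers import MethMatrix
from .synthetic import SMOKING_PROBE

BETA_CLIP = 1e-6


def beta_to_m(beta, clip: float = BETA_CLIP):
    """M = log2(beta / (1 - beta)) after clipping beta into
    [clip, 1 - clip] to avoid infinities."""
    b = np.clip(np.asarray(beta, dtype=float), clip, 1.0 - clip)
    out = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index, name=beta.name)
    return out

def m_to_beta(m):
    """Exact inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    a = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-a))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(out, index=m.index, name=m.name)
    return out


@dataclass
class ProbeFilterReport:
    """Per-probe pass/fail flags, stage-wise retained counts, final set."""

    flags: pd.DataFrame  # boolean columns per filter + "retained"
    counts: dict  # stage name -> cumulative retained count
    retained: pd.Index
    n_missing_r: int = 0


def filter_probes(
    meth: MethMatrix,
    blood_variable_ids=None,
    blood_brain_r: pd.Series | None = None,
    range_min: float = 0.05,
    r_min: float = 0.3,
    use_brain_filter: bool = True,
    drop_probe_snps: bool = True,
) -> ProbeFilterReport:
    """Select the analysis CpG set.

    ``blood_variable_ids`` and ``blood_brain_r`` default to the manifest
    columns ``blood_variable`` / ``blood_brain_r`` when present.  A probe
    with no blood-brain r is treated as failing that filter (counted in
    ``n_missing_r``).  The variability rule is strict: q90 - q10 > range_min.
    """
    beta = meth.beta
    probes = beta.index
    q10 = beta.quantile(0.10, axis=1)
    q90 = beta.quantile(0.90, axis=1)
    variability = (q90 - q10) > range_min

    if blood_variable_ids is None:
        if "blood_variable" in meth.manifest.columns:
            blood = meth.manifest["blood_variable"].reindex(probes).fillna(False)
        else:
            blood = pd.Series(True, index=probes)
    else:
        blood = probes.isin(pd.Index(blood_variable_ids))
        blood = pd.Series(blood, index=probes)

    n_missing_r = 0
    if use_brain_filter:
        if blood_brain_r is None and "blood_brain_r" in meth.manifest.columns:
            blood_brain_r = meth.manifest["blood_brain_r"]
        if blood_brain_r is None:
            raise ValueError("brain filter requested but no blood-brain r given")
        r = blood_brain_r.reindex(probes)
        n_missing_r = int(r.isna().sum())
        brain = r.abs() >= r_min
        brain = brain.fillna(False)
    else:
        brain = pd.Series(True, index=probes)

    if drop_probe_snps:
        no_snp = ~meth.manifest["probe_snp"].reindex(probes).fillna(False).astype(bool)
    else:
        no_snp = pd.Series(True, index=probes)

    flags = pd.DataFrame(
        {
            "variability": variability.astype(bool),
            "blood_list": blood.astype(bool),
            "brain_corr": brain.astype(bool),
            "no_probe_snp": no_snp.astype(bool),
        }
    )
    flags["retained"] = flags.all(axis=1)
    # cumulative counts in the fixed reporting order
    counts = {"input": int(len(probes))}
    cum = pd.Series(True, index=probes)
    for stage in ("variability", "blood_list", "brain_corr", "no_probe_snp"):
        cum &= flags[stage]
        counts[stage] = int(cum.sum())
    return ProbeFilterReport(flags, counts, probes[flags["retained"]], n_missing_r)


def estimate_cell_counts(
    meth_or_beta, reference: pd.DataFrame, min_overlap: int = 10
) -> pd.DataFrame:
    """Reference-based (Houseman-style) cell-fraction estimation.

    Per sample solves min ||x - R w||^2 subject to w >= 0, sum(w) <= 1 on
    the beta scale, where R holds purified cell-type reference profiles.
    Returns samples x cell-types fractions.
    """
    beta = meth_or_beta.beta if isinstance(meth_or_beta, MethMatrix) else meth_or_beta
    shared = beta.index.intersection(reference.index)
    if len(shared) < min_overlap:
        raise ValueError(
            f"only {len(shared)} probes overlap the reference (need {min_overlap})"
        )
    r = reference.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(r) < r.shape[1]:
        corr = np.corrcoef(r.T)
        bad = [
            f"{reference.columns[i]}~{reference.columns[j]}"
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 1 - 1e-9
        ]
        raise ValueError(f"reference is rank-deficient; collinear cell types: {bad}")
    x_all = beta.loc[shared].to_numpy(dtype=float)
    k = r.shape[1]
    rtr = r.T @ r
    out = np.empty((beta.shape[1], k))
    cons = ({"type": "ineq", "fun": lambda w: 1.0 - w.sum(),
             "jac": lambda w: -np.ones_like(w)},)
    bounds = [(0.0, 1.0)] * k
    for s in range(beta.shape[1]):
        x = x_all[:, s]
        rtx = r.T @ x

        def objective(w, rtx=rtx):
            return float(w @ rtr @ w - 2.0 * rtx @ w)

        def gradient(w, rtx=rtx):
            return 2.0 * (rtr @ w - rtx)

        w0 = np.full(k, 1.0 / (k + 1))
        res = minimize(objective, w0, jac=gradient, bounds=bounds,
                       constraints=cons, method="SLSQP",
                       options={"maxiter": 500, "ftol": 1e-14})
        out[s] = np.clip(res.x, 0.0, None)
    return pd.DataFrame(out, index=beta.columns, columns=reference.columns)


def infer_smoking(
    meth: MethMatrix, probe: str = SMOKING_PROBE, beta_cut: float = 0.75
) -> pd.Series:
    """Probable-smoker flags from the AHRR sentinel probe.

    A sample is flagged when beta < beta_cut (strict: beta == beta_cut is
    a non-smoker).
    """
    if probe not in meth.beta.index:
        raise ValueError(
            f"probe {probe!r} absent from the matrix; check the manifest/QC chain"
        )
    flags = meth.beta.loc[probe] < beta_cut
    flags.name = "probable_smoker"
    return flags
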