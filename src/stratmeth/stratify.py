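"""Quintile stratification of polygenic scores, poly-methylomic profile
scores (PMPS), and the validation statistical models.

The High/Low comparator groups are the top and bottom two quintiles of
the score distribution: round(0.4 * n) samples each (half-up), so
n = 103 gives 41/41 and n = 67 gives 27/27.  A PMPS is the methylation
analogue of a PRS: a per-sample weighted sum of beta values at CpGs
passing a discovery-EWAS p threshold, weighted by the discovery
coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EwasTable, MethMatrix
from .methqc import beta_to_m

#: PMPS selection thresholds evaluated in validation.
DEFAULT_PMPS_THRESHOLDS = (0.002, 0.01, 0.05)


@dataclass
class StratumAssignment:
    assignments: pd.Series  # values in {"Low", "Mid", "High"}
    counts: dict
    cutpoints: tuple  # (max Low score, min High score)

    @property
    def low(self) -> pd.Index:
        return self.assignments.index[self.assignments == "Low"]

    @property
    def high(self) -> pd.Index:
        return self.assignments.index[self.assignments == "High"]


def quintile_strata(prs: pd.Series, fraction: float = 0.4) -> StratumAssignment:
    """Top/bottom-two-quintile strata of a score vector.

    k = round(fraction * n), half-up; the k lowest scores form Low, the k
    highest form High, the remainder Mid.  Ties are broken by stable
    sample-id order so membership is invariant to input order.
    """
    n = len(prs)
    if n < 5:
        raise ValueError("need at least 5 samples to form quintile strata")
    k = int(math.floor(fraction * n + 0.5))
    order = prs.sort_index().sort_values(kind="stable").index
    labels = pd.Series("Mid", index=prs.index, name="stratum")
    labels.loc[order[:k]] = "Low"
    labels.loc[order[-k:]] = "High"
    counts = labels.value_counts().to_dict()
    cut = (float(prs.loc[order[k - 1]]), float(prs.loc[order[-k]]))
    return StratumAssignment(labels, counts, cut)


@dataclass
class PmpsTable:
    scores: pd.Series
    p_threshold: float
    n_cpgs: int
    n_dropped: int
    weight_field: str
    scale: str
    aggregate: str


def compute_pmps(
    target_meth,
    discovery: EwasTable | pd.DataFrame,
    p_threshold: float = 0.05,
    weight_field: str = "coef",
    p_field: str = "p_corr",
    scale: str = "beta",
    aggregate: str = "sum",
) -> PmpsTable:
    """Per-sample PMPS in an independent target set.

    PMPS_i = sum_{j: p_j < p_T} b_j * beta_ij over probes present in the
    target after its QC; absent probes are silently dropped and counted.
    ``scale`` = "m" scores M-values instead of beta; ``aggregate`` = "mean"
    divides by the number of included CpGs.
    """
    disc = discovery.table if isinstance(discovery, EwasTable) else discovery
    beta = target_meth.beta if isinstance(target_meth, MethMatrix) else target_meth
    selected = disc.index[disc[p_field] < p_threshold]
    present = selected.intersection(beta.index)
    n_dropped = len(selected) - len(present)
    if len(present) == 0:
        raise ValueError(
            f"no probes below p_T={p_threshold} overlap the target matrix"
        )
    values = beta.loc[present]
    if scale == "m":
        values = beta_to_m(values)
    weights = disc.loc[present, weight_field].to_numpy()
    scores = pd.Series(values.to_numpy().T @ weights, index=beta.columns,
                       name="pmps")
    if aggregate == "mean":
        scores = scores / len(present)
    return PmpsTable(scores, p_threshold, int(len(present)), int(n_dropped),
                     weight_field, scale, aggregate)


# ---------------------------------------------------------------------------
# validation GLMs (type-III F, partial eta^2, Shapiro-Wilk)
# ---------------------------------------------------------------------------

@dataclass
class GlmReport:
    terms: pd.DataFrame  # per-term df, ss, F (or wald_chi2), p, eta2p
    shapiro: pd.DataFrame  # per-group W, p for the outcome
    residual_df: int
    residual_ss: float
    omnibus_p: float | None = None
    extras: dict = field(default_factory=dict)


def _effect_code(series: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero coding for a categorical: levels sorted, last is baseline."""
    levels = sorted(pd.unique(series.astype(str)))
    cols = []
    names = []
    for lev in levels[:-1]:
        col = np.where(series.astype(str) == lev, 1.0, 0.0)
        col[series.astype(str) == levels[-1]] = -1.0
        cols.append(col)
        names.append(f"{series.name}[{lev}]")
    return np.column_stack(cols), names


def _term_columns(data: pd.DataFrame, term: str) -> tuple[np.ndarray, list]:
    """Design columns for one term; ``a:b`` denotes an interaction."""
    if ":" in term:
        parts = term.split(":")
        mats = [_term_columns(data, p)[0] for p in parts]
        out = mats[0]
        for m in mats[1:]:
            out = np.einsum("ij,ik->ijk", out, m).reshape(len(out), -1)
        return out, [term]
    s = data[term]
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        return _effect_code(s)
    return s.to_numpy(dtype=float)[:, None], [term]


def type3_anova(data: pd.DataFrame, outcome: str, terms: list) -> GlmReport:
    """OLS with type-III sums of squares per term (model-comparison SS on
    effects-coded factors) and partial eta^2 = SS_term/(SS_term + SS_resid)."""
    y = data[outcome].to_numpy(dtype=float)
    n = len(y)
    blocks = {}
    for t in terms:
        cols, _ = _term_columns(data, t)
        blocks[t] = cols
    full = np.hstack([np.ones((n, 1))] + [blocks[t] for t in terms])

    def ssr(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r)

    sse_full = ssr(full)
    df_resid = n - np.linalg.matrix_rank(full)
    rows = []
    for t in terms:
        reduced = np.hstack(
            [np.ones((n, 1))] + [blocks[u] for u in terms if u != t]
        )
        ss_term = max(ssr(reduced) - sse_full, 0.0)
        df_term = blocks[t].shape[1]
        f = (ss_term / df_term) / (sse_full / df_resid) if df_resid > 0 else np.inf
        p = float(stats.f.sf(f, df_term, df_resid))
        eta2p = ss_term / (ss_term + sse_full) if (ss_term + sse_full) > 0 else 0.0
        rows.append((t, df_term, ss_term, f, p, eta2p))
    table = pd.DataFrame(rows, columns=["term", "df", "ss", "F", "p", "eta2p"])
    table = table.set_index("term")
    # omnibus F vs intercept-only
    sse_null = ssr(np.ones((n, 1)))
    df_model = np.linalg.matrix_rank(full) - 1
    if df_model > 0 and df_resid > 0:
        f_omni = ((sse_null - sse_full) / df_model) / (sse_full / df_resid)
        omni_p = float(stats.f.sf(f_omni, df_model, df_resid))
    else:
        omni_p = None
    return GlmReport(table, pd.DataFrame(), int(df_resid), sse_full,
                     omnibus_p=omni_p)


def _shapiro_by_group(outcome: pd.Series, groups: pd.Series) -> pd.DataFrame:
    rows = []
    for g, vals in outcome.groupby(groups.astype(str)):
        if len(vals) >= 3:
            w, p = stats.shapiro(vals.to_numpy())
        else:
            w, p = np.nan, np.nan
        rows.append((g, float(w), float(p), len(vals)))
    return pd.DataFrame(rows, columns=["group", "W", "p", "n"]).set_index("group")


def validate_glm(
    data: pd.DataFrame,
    outcome: str = "pmps",
    group: str = "group",
    covariates=(),
    prs: str | None = None,
    include_interaction: bool = False,
) -> GlmReport:
    """Univariate GLM of PMPS on group (+ covariates, optional PRS and
    PRS x group interaction); type-III F, partial eta^2 and per-group
    Shapiro-Wilk normality of the outcome."""
    counts = data[group].value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"groups with < 3 members: {small}")
    terms = [group] + list(covariates)
    if prs is not None:
        terms.append(prs)
        if include_interaction:
            terms.append(f"{prs}:{group}")
    report = type3_anova(data, outcome, terms)
    report.shapiro = _shapiro_by_group(data[outcome], data[group])
    return report


def faces_model(
    data: pd.DataFrame,
    outcome: str = "pmps",
    faces: str = "faces",
    prs: str = "prs",
    group: str = "group",
    covariates=("age", "sex"),
) -> GlmReport:
    """Exploratory family-environment model.

    Linear model with terms FACES, PRS, group, PRS x group, FACES x group
    plus covariates; per single-df term a Wald chi-square = (coef/SE)^2
    with chi-square(1) p, and the omnibus model F p.
    """
    if data[faces].nunique() <= 1:
        raise ValueError("FACES scores are constant; model not identifiable")
    terms = [faces, prs, group, f"{prs}:{group}", f"{faces}:{group}"]
    terms += list(covariates)
    y = data[outcome].to_numpy(dtype=float)
    n = len(y)
    cols = [np.ones((n, 1))]
    names = ["const"]
    for t in terms:
        c, nm = _term_columns(data, t)
        cols.append(c)
        names.extend(nm if len(nm) == c.shape[1] else
                     [f"{t}[{i}]" for i in range(c.shape[1])])
    x = np.hstack(cols)
    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    df_resid = n - np.linalg.matrix_rank(x)
    s2 = resid @ resid / df_resid
    se = np.sqrt(np.diag(xtx_inv) * s2)
    wald = (beta / se) ** 2
    p = stats.chi2.sf(wald, df=1)
    table = pd.DataFrame(
        {"coef": beta, "se": se, "wald_chi2": wald, "p": p}, index=names
    ).drop(index="const")
    sse_null = float(((y - y.mean()) ** 2).sum())
    sse_full = float(resid @ resid)
    df_model = np.linalg.matrix_rank(x) - 1
    f_omni = ((sse_null - sse_full) / df_model) / (sse_full / df_resid)
    omni_p = float(stats.f.sf(f_omni, df_model, df_resid))
    report = GlmReport(table, _shapiro_by_group(data[outcome], data[group]),
                       int(df_resid), sse_full, omnibus_p=omni_p)
    return report
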