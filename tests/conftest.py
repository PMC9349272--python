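"""Shared fixtures: small synthetic studies reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from stratmeth.containers import SnpPanel
from stratmeth.synthetic import CohortConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """An 80-sample cohort with strong planted effects, shared read-only."""
    cfg = CohortConfig(
        n_samples=80, n_snps=400, n_blocks=20, n_probes=600,
        coupling_effect=0.8, n_coupled_probes=20, seed=1234,
    )
    return simulate_study(cfg, cohorts={"discovery": 80})


@pytest.fixture(scope="session")
def small_cohort(small_study):
    return small_study["discovery"]


def make_panel(dosages: np.ndarray, maf=None, chrom=None, pos=None,
               a1=None, a2=None, info=None, sample_ids=None) -> SnpPanel:
    """Hand-build a SnpPanel from a samples x variants dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = pd.Index([f"snp{j}" for j in range(m)], name="snp")
    freq = np.nanmean(dosages, axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else 1 + 1000 * np.arange(m),
            "a1": a1 if a1 is not None else ["A"] * m,
            "a2": a2 if a2 is not None else ["G"] * m,
            "maf": maf if maf is not None else np.minimum(freq, 1 - freq),
            "info": info if info is not None else np.ones(m),
        },
        index=ids,
    )
    samples = pd.Index(
        sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)],
        name="sample",
    )
    return SnpPanel(variants, pd.DataFrame(dosages, index=samples, columns=ids))


def make_summary(panel: SnpPanel, beta, p, a1=None, a2=None) -> pd.DataFrame:
    """Matching GWAS summary frame for a hand-built panel."""
    v = panel.variants
    m = len(v)
    se = np.full(m, 0.05)
    return pd.DataFrame(
        {
            "chrom": v["chrom"],
            "pos": v["pos"],
            "a1": a1 if a1 is not None else v["a1"],
            "a2": a2 if a2 is not None else v["a2"],
            "beta": np.asarray(beta, dtype=float),
            "se": se,
            "p": np.asarray(p, dtype=float),
        },
        index=v.index,
    )
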