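"""End-to-end orchestration of the synthetic study pipeline.

Stages run in dependency order (simulate -> prs -> strata -> methqc ->
ewas -> pmps -> validate -> enrich) from a single YAML-style config dict;
every stage writes its outputs under the run directory together with a
JSON provenance block (input hashes, settings, seed, package version).
Re-running with the same config and seed reproduces identical output
hashes for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .enrich import build_domains, enrich as run_enrich, map_probes
from .ewas import run_ewas
from .methqc import beta_to_m, estimate_cell_counts, filter_probes, infer_smoking
from .prs import filter_variants, ld_clump, mds_ancestry, optimize_threshold, score_prs
from .stratify import (DEFAULT_PMPS_THRESHOLDS, compute_pmps, quintile_strata,
                       validate_glm)
from .synthetic import CohortConfig, simulate_study

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {},  # CohortConfig overrides
    "validation_n": 67,
    "prs": {
        "maf_min": 0.05,
        "info_min": 0.8,
        "clump_kb": 250.0,
        "clump_r2": 0.1,
        "p_threshold": "optimize",
    },
    "strata": {"fraction": 0.4},
    "methqc": {"range_min": 0.05, "r_min": 0.3, "use_brain_filter": True},
    "ewas": {
        "moderate_var": True,
        "n_sv": "auto",
        "bacon_iters": 5000,
        "bacon_burnin": 2000,
        "alpha": 0.05,
    },
    "pmps": {"thresholds": list(DEFAULT_PMPS_THRESHOLDS)},
    "enrich": {"fdr": 0.05, "mode": "union",
               "basal_up": 5000, "basal_down": 1000, "distal": 5000},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Accumulates stage outputs and provenance under one directory."""

    def __init__(self, out_dir, config: dict):
        self.dir = Path(out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.config = config
        self.manifest: dict = {"version": __version__, "config": config,
                               "stages": {}}

    def record(self, stage: str, outputs: dict, settings: dict,
               counts: dict | None = None) -> None:
        entry = {
            "settings": settings,
            "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                        for k, p in outputs.items()},
        }
        if counts:
            entry["counts"] = counts
            logger.info("stage %s counts: %s", stage, counts)
        self.manifest["stages"][stage] = entry
        with open(self.dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def run_pipeline(config: dict | None = None, out_dir="pipeline_run") -> PipelineRun:
    """Run every stage of the synthetic-study pipeline.

    Returns the :class:`PipelineRun`; all numeric outputs live in stage
    TSVs under ``out_dir`` and are hash-recorded in ``manifest.json``.
    Raises with the stage name on failure, keeping partial outputs.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    run = PipelineRun(out_dir, cfg)
    stage = "simulate"
    try:
        t0 = time.time()
        ccfg = CohortConfig(**_merge({"seed": cfg["seed"]}, cfg["cohort"]))
        study = simulate_study(
            ccfg,
            cohorts={"discovery": ccfg.n_samples,
                     "validation": cfg["validation_n"]},
        )
        disc = study["discovery"]
        vali = study["validation"]
        outputs = {}
        for name, cohort in study.cohorts.items():
            v, d = io.write_snp_panel(cohort.panel, run.dir / f"{name}.geno")
            b, m = io.write_meth_matrix(cohort.meth, run.dir / name)
            s = io.write_sample_sheet(cohort.samples, run.dir / f"{name}.samples.tsv")
            outputs.update({f"{name}_variants": v, f"{name}_dosage": d,
                            f"{name}_beta": b, f"{name}_manifest": m,
                            f"{name}_samples": s})
        outputs["summary"] = io.write_gwas_summary(study.summary,
                                                   run.dir / "gwas_summary.tsv")
        run.record(stage, outputs, ccfg.to_dict(),
                   {"n_discovery": disc.panel.n_samples,
                    "n_validation": vali.panel.n_samples,
                    "n_snps": disc.panel.n_snps,
                    "n_probes": len(disc.meth.beta)})

        stage = "prs"
        pcfg = cfg["prs"]
        results = {}
        for name, cohort in study.cohorts.items():
            panel_f, summary_f, _ = filter_variants(
                cohort.panel, study.summary,
                maf_min=pcfg["maf_min"], info_min=pcfg["info_min"])
            kept = ld_clump(panel_f, summary_f, window_kb=pcfg["clump_kb"],
                            r2_max=pcfg["clump_r2"])
            panel_c = panel_f.subset_variants(kept)
            if pcfg["p_threshold"] == "optimize":
                pheno = cohort.samples["case"].where(
                    cohort.samples["group"] != "HR")
                p_t, profile = optimize_threshold(panel_c, summary_f, pheno)
                profile.to_csv(run.dir / f"{name}.prs_profile.tsv", sep="\t",
                               index=False)
            else:
                p_t = float(pcfg["p_threshold"])
            res = score_prs(panel_c, summary_f, p_t)
            mds = mds_ancestry(panel_c, k=4)
            frame = res.scores.join(mds[["C1", "C2"]])
            frame["p_t"] = p_t
            path = run.dir / f"{name}.prs.tsv"
            frame.rename_axis("sample").to_csv(path, sep="\t")
            results[name] = (res, mds)
            outputs = {f"{name}_prs": path}
            run.record(f"{stage}:{name}", outputs,
                       {**pcfg, "p_t_used": p_t},
                       {"n_snps_scored": res.n_snps_included})

        stage = "strata"
        strata = {}
        for name in study.cohorts:
            res, _ = results[name]
            sa = quintile_strata(res.scores["std"],
                                 fraction=cfg["strata"]["fraction"])
            strata[name] = sa
            path = run.dir / f"{name}.strata.tsv"
            sa.assignments.rename_axis("sample").to_frame().to_csv(path, sep="\t")
            run.record(f"{stage}:{name}", {f"{name}_strata": path},
                       cfg["strata"], sa.counts)

        stage = "methqc"
        qcfg = cfg["methqc"]
        filtered = {}
        for name, cohort in study.cohorts.items():
            rep = filter_probes(cohort.meth, range_min=qcfg["range_min"],
                                r_min=qcfg["r_min"],
                                use_brain_filter=qcfg["use_brain_filter"])
            cells = estimate_cell_counts(cohort.meth,
                                         cohort.truth.cell_reference)
            smoking = infer_smoking(cohort.meth)
            fpath = run.dir / f"{name}.probes_retained.tsv"
            rep.flags.rename_axis("probe").to_csv(fpath, sep="\t")
            cpath = run.dir / f"{name}.cell_counts.tsv"
            cells.rename_axis("sample").to_csv(cpath, sep="\t")
            spath = run.dir / f"{name}.smoking.tsv"
            smoking.rename_axis("sample").to_frame().to_csv(spath, sep="\t")
            filtered[name] = (rep, cells, smoking)
            run.record(f"{stage}:{name}",
                       {"flags": fpath, "cells": cpath, "smoking": spath},
                       qcfg, rep.counts)

        stage = "ewas"
        ecfg = cfg["ewas"]
        rep, cells, smoking = filtered["discovery"]
        sa = strata["discovery"]
        analysed = sa.low.union(sa.high)
        res, mds = results["discovery"]
        samples = disc.samples.loc[analysed].copy()
        samples["stratum"] = (sa.assignments.loc[analysed] == "High").astype(float)
        samples = samples.join(mds.loc[analysed, ["C1", "C2"]])
        samples = samples.join(cells.loc[analysed])
        mvals = beta_to_m(disc.meth.beta.loc[rep.retained, analysed])
        covs = ["sex", "age", "C1", "C2", "tissue",
                *cells.columns.tolist()]
        ewas = run_ewas(
            mvals, samples, predictor="stratum", covariates=covs,
            n_sv=ecfg["n_sv"], moderate_var=ecfg["moderate_var"],
            bacon_iters=ecfg["bacon_iters"], bacon_burnin=ecfg["bacon_burnin"],
            alpha=ecfg["alpha"], seed=cfg["seed"],
            manifest=disc.meth.manifest,
        )
        epath = run.dir / "discovery.ewas.tsv"
        ewas.table.rename_axis("probe").to_csv(epath, sep="\t",
                                               float_format="%.6g")
        run.record(stage, {"ewas": epath},
                   {**ecfg, "bias": ewas.bias, "inflation": ewas.inflation,
                    "bonferroni": ewas.bonferroni, "n_sv": ewas.n_sv},
                   {"n_probes_tested": ewas.n_probes,
                    "n_samples": len(analysed),
                    "n_significant": int(ewas.table["pass_bonferroni"].sum())})

        stage = "pmps"
        vrep, vcells, _ = filtered["validation"]
        pmps_tables = {}
        pframe = pd.DataFrame(index=vali.meth.sample_ids)
        for p_t in cfg["pmps"]["thresholds"]:
            target = vali.meth.subset_probes(
                vrep.retained.intersection(ewas.table.index))
            tab = compute_pmps(target, ewas, p_threshold=p_t)
            pmps_tables[p_t] = tab
            pframe[f"pmps_{p_t}"] = tab.scores
        ppath = run.dir / "validation.pmps.tsv"
        pframe.rename_axis("sample").to_csv(ppath, sep="\t")
        run.record(stage, {"pmps": ppath}, cfg["pmps"],
                   {f"n_cpgs_{p}": t.n_cpgs for p, t in pmps_tables.items()})

        stage = "validate"
        vsa = strata["validation"]
        van = vsa.low.union(vsa.high)
        vdata = vali.samples.loc[van].copy()
        vdata["stratum"] = np.where(vsa.assignments.loc[van] == "High",
                                    "High", "Low")
        last_pt = cfg["pmps"]["thresholds"][-1]
        vdata["pmps"] = pframe.loc[van, f"pmps_{last_pt}"]
        vdata = vdata.join(vcells.loc[van])
        report = validate_glm(vdata, outcome="pmps", group="stratum",
                              covariates=["age", "sex", "tissue",
                                          *vcells.columns.tolist()])
        vpath = run.dir / "validation.glm.tsv"
        report.terms.to_csv(vpath, sep="\t", float_format="%.6g")
        run.record(stage, {"glm": vpath}, {"p_t": last_pt},
                   {"n": len(vdata)})

        stage = "enrich"
        ncfg = cfg["enrich"]
        genes = _toy_gene_models(disc.meth.manifest)
        domains = build_domains(genes, basal_up=ncfg["basal_up"],
                                basal_down=ncfg["basal_down"],
                                distal=ncfg["distal"])
        inflection = 0.002
        dmp_ids = ewas.table.index[ewas.table["p_corr"] < 0.05]
        dmps = disc.meth.manifest.loc[dmp_ids, ["chrom", "pos"]]
        mapping, gene_list = map_probes(dmps, genes, domains,
                                        mode=ncfg["mode"])
        background = sorted(genes["gene"].unique())
        sets = _toy_gene_sets(background)
        enr = run_enrich(gene_list, sets, background)
        np_path = run.dir / "enrichment.tsv"
        enr.to_csv(np_path, sep="\t", float_format="%.6g")
        mpath = run.dir / "probe_gene_map.tsv"
        mapping.to_csv(mpath, sep="\t", index=False)
        run.record(stage, {"enrichment": np_path, "mapping": mpath},
                   {**ncfg, "inflection": inflection},
                   {"n_dmps": len(dmps), "n_genes": len(gene_list),
                    "n_significant_sets": int((enr["q"] <= ncfg["fdr"]).sum())})
        logger.info("pipeline complete in %.1f s", time.time() - t0)
        return run
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _toy_gene_models(manifest: pd.DataFrame) -> pd.DataFrame:
    """Gene models consistent with a synthetic manifest's gene annotation:
    one model per annotated gene spanning its probes."""
    rows = []
    for gene, sub in manifest.groupby("gene"):
        if not gene:
            continue
        chrom = sub["chrom"].iloc[0]
        sub = sub[sub["chrom"] == chrom]
        start, end = int(sub["pos"].min()), int(sub["pos"].max()) + 1000
        rows.append((gene, chrom, "+", start, start, end))
    return pd.DataFrame(rows, columns=["gene", "chrom", "strand", "tss",
                                       "start", "end"])


def _toy_gene_sets(background, n_sets: int = 20, size: int = 50,
                   seed: int = 13) -> dict:
    rng = np.random.default_rng(seed)
    bg = list(background)
    return {
        f"SET{i:02d}": list(rng.choice(bg, size=min(size, len(bg)),
                                       replace=False))
        for i in range(n_sets)
    }
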