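"""End-to-end orchestration of the synthetic signature-discovery experiment.

One call runs: simulate -> per-condition/per-year association scans ->
seed-network module analysis -> cross-condition core overlap and signature
selection -> quartile classification (clinical vs clinical + transcriptome)
-> methylation mapping, and scores recovery against the planted truth.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import associate, classify, methyl, netmod, signature as sigmod, simulate
from .datatypes import CONDITIONS, N_YEARS, CohortPhenotype
from .io import PipelineConfig, write_report

__all__ = ["run_pipeline", "RunManifest", "simulate_inputs", "condition_covariates"]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict[str, Any]
    seeds: dict[str, int]
    hashes: dict[str, str]
    timings: dict[str, float]
    cores: dict[str, list[str]]
    signatures: dict[int, sigmod.Signature]
    overlap_table: pd.DataFrame
    classification: pd.DataFrame
    methylation_tally: methyl.DirectionTally | None
    methylation_map: pd.DataFrame | None
    recovery: dict[str, float] = field(default_factory=dict)

    def signature_union(self) -> set[str]:
        union: set[str] = set()
        for sig in self.signatures.values():
            union |= sig.genes
        return union


def _hash_frame(df: pd.DataFrame) -> str:
    payload = pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()
    return hashlib.sha256(payload).hexdigest()[:16]


def simulate_inputs(config: PipelineConfig, seed: int):
    """Generate interactome, truth, cohort, genotypes and methylation."""
    graph, membership = simulate.generate_interactome(
        config.n_genes_interactome, [config.module_size],
        config.p_in, config.p_out, seed=seed,
    )
    planted = sorted(g for g, m in membership.items() if m == 0)
    truth = simulate.default_truth(
        planted, seed=seed + 1,
        clinical_r2=config.clinical_r2,
        bio_r2=config.bio_r2,
        neg_methyl_fraction=config.neg_methyl_fraction,
        null=config.null_effects,
    )
    expr, pheno = simulate.generate_cohort(
        truth, graph, {"GHD": config.n_ghd, "TS": config.n_ts},
        config.n_genes_expressed, seed=seed + 2,
    )
    geno = simulate.generate_genotypes(
        config.n_markers, config.n_ld_blocks, pheno, None, seed=seed + 3
    )
    ghd = pheno.condition("GHD")
    sub = CohortPhenotype(ghd.table.iloc[: config.n_methyl_samples].copy())
    meth_mat = simulate.generate_methylation(
        truth, sub, config.n_methyl_genes, seed=seed + 4
    )
    return graph, truth, expr, pheno, geno, meth_mat, sub


def condition_covariates(pheno: pd.DataFrame, condition: str, year: int) -> pd.DataFrame:
    """Covariates eliminated before the year's scan.

    Microarray batch, age and baseline BMI for both conditions; sex and the
    peak GH stimulation response for GHD; plus the year's Tanner stage as an
    ordinal indicator set to absorb pubertal growth.
    """
    cov = pheno[["batch", "age", "bmi_sds"]].copy()
    if condition == "GHD":
        cov["sex"] = pheno["sex"]
        cov["peak_gh"] = pheno["peak_gh"]
    cov["tanner"] = pheno[f"tanner{year}"].astype(str)
    return cov


def _endpoint_series(pheno: pd.DataFrame, year: int, endpoint: str) -> pd.Series:
    if endpoint == "cumulative":
        return pheno[[f"hv{y}" for y in range(1, N_YEARS + 1)]].sum(axis=1, min_count=1)
    return pheno[f"hv{year}"]


def run_pipeline(
    config: PipelineConfig,
    seed: int | None = None,
    outdir: str | None = None,
) -> RunManifest:
    """Run the full synthetic experiment for both conditions and all years."""
    seed = config.seed if seed is None else seed
    t_start = time.perf_counter()
    timings: dict[str, float] = {}

    graph, truth, expr, pheno, geno, meth_mat, meth_pheno = simulate_inputs(config, seed)
    timings["simulate"] = time.perf_counter() - t_start
    universe_genes = sorted(set(expr.gene_ids) & set(graph.nodes))
    universe = len(universe_genes)

    assoc_tables: dict[tuple[str, int], pd.DataFrame] = {}
    cores: dict[str, list[str]] = {}
    t0 = time.perf_counter()
    for cond in CONDITIONS:
        sub = pheno.condition(cond)
        for year in range(1, N_YEARS + 1):
            resp = _endpoint_series(sub.table, year, config.endpoint).dropna()
            cov = condition_covariates(sub.table.loc[resp.index], cond, year)
            table = associate.rank_regression_scan(
                expr.subset_samples(resp.index), resp, cov, alpha=config.assoc_p
            )
            assoc_tables[(cond, year)] = table
            seeds_genes = set(table.loc[table["flagged"], "feature_id"])
            if not seeds_genes:
                cores[f"{cond}_y{year}"] = []
                continue
            net = netmod.build_seed_network(seeds_genes, graph)
            landscape = netmod.detect_overlapping_modules(
                net, lam=config.landscape_lambda, depth=config.landscape_depth,
                tau=config.membership_tau,
            )
            metanodes = [
                netmod.module_core(landscape, mod, k=config.metanode_size)
                for mod in landscape.modules
            ]
            cores[f"{cond}_y{year}"] = sorted(netmod.network_core(metanodes))
    timings["associate_netmod"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    signatures: dict[int, sigmod.Signature] = {}
    for year in range(1, N_YEARS + 1):
        core_g = cores.get(f"GHD_y{year}", [])
        core_t = cores.get(f"TS_y{year}", [])
        shared, p_overlap = sigmod.core_overlap_test(core_g, core_t, universe)
        signatures[year] = sigmod.select_signature(
            shared, assoc_tables[("GHD", year)], assoc_tables[("TS", year)],
            alpha=config.signature_p, year=year, overlap_p=p_overlap,
            core_ghd=core_g, core_ts=core_t,
        )
    overlap_table = sigmod.yearwise_overlap_summary(cores, universe,
                                                    flag_alpha=config.overlap_p)
    timings["signature"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rows = []
    for cond in CONDITIONS:
        sub = pheno.condition(cond)
        for year in range(1, N_YEARS + 1):
            resp = _endpoint_series(sub.table, year, config.endpoint).dropna()
            if len(resp) < 8:
                continue
            labels = classify.quartile_labels(resp, endpoint=f"{cond}_hv{year}")
            sig_genes = sorted(signatures[year].genes & set(expr.gene_ids))
            sig_expr = expr.data.loc[sig_genes]
            clin = CohortPhenotype(sub.table.loc[resp.index]).clinical_features()
            for task in ("low", "high"):
                y = labels.task(task)
                rep_clin, rep_comb, deltas = classify.compare_phenotype_models(
                    clin, sig_expr, y, n_trees=config.rf_trees,
                    seed=seed + 1000 + year * 10 + (task == "high"),
                    smote_k=config.smote_k,
                )
                for feats, rep in (("clinical", rep_clin),
                                   ("clinical+transcriptome", rep_comb)):
                    rows.append({
                        "condition": cond, "year": year, "quartile": task,
                        "features": feats, "n": len(y),
                        "n_signature_genes": len(sig_genes),
                        "auc": rep.auc, "auc_ci_lo": rep.auc_ci[0],
                        "auc_ci_hi": rep.auc_ci[1], "oob_error": rep.oob_error,
                    })
    classification = pd.DataFrame(rows)
    timings["classify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    meth_resp = meth_pheno.table["hv1"]
    _, tally = methyl.methylation_response_scan(meth_mat, meth_resp,
                                                alpha=config.methyl_p)
    union = set().union(*(s.genes for s in signatures.values())) if signatures else set()
    meth_map = methyl.map_signature_methylation(union, meth_mat, meth_resp,
                                                r_threshold=config.methyl_r)
    timings["methyl"] = time.perf_counter() - t0

    planted = set(truth.planted_module_genes)
    recovery: dict[str, float] = {}
    if planted:
        hits = union & planted
        recovery["signature_sensitivity"] = len(hits) / len(planted)
        recovery["signature_precision"] = (len(hits) / len(union)) if union else np.nan
        recovery["signature_union_size"] = float(len(union))
        comb = classification[classification["features"] == "clinical+transcriptome"]
        clin_only = classification[classification["features"] == "clinical"]
        merged = comb.merge(clin_only, on=["condition", "year", "quartile"],
                            suffixes=("_comb", "_clin"))
        recovery["mean_delta_auc"] = float(
            (merged["auc_comb"] - merged["auc_clin"]).mean()
        )
        recovery["uplift_fraction"] = float(
            (merged["auc_comb"] > merged["auc_clin"]).mean()
        )
        recovery["methyl_negative_share"] = tally.negative_share

    manifest = RunManifest(
        config=config.to_dict(),
        seeds={"root": seed},
        hashes={
            "expression": _hash_frame(expr.data),
            "phenotype": _hash_frame(pheno.table),
            "genotypes": _hash_frame(geno.calls),
            "methylation": _hash_frame(meth_mat.data),
            "classification": _hash_frame(classification) if len(classification) else "",
        },
        timings=timings,
        cores=cores,
        signatures=signatures,
        overlap_table=overlap_table,
        classification=classification,
        methylation_tally=tally,
        methylation_map=meth_map,
        recovery=recovery,
    )

    if outdir is not None:
        sig_table = pd.concat(
            [s.provenance.assign(year=yr) for yr, s in signatures.items()],
            ignore_index=True,
        ) if signatures else pd.DataFrame()
        write_report(
            {
                "classification": classification,
                "overlap": overlap_table,
                "signatures": sig_table,
                "methylation_map": meth_map,
                "config": manifest.config,
                "seeds": manifest.seeds,
                "hashes": manifest.hashes,
                "timings": timings,
                "recovery": recovery,
                "cores": cores,
                "signature_genes": {str(y): sorted(s.genes) for y, s in signatures.items()},
                "methylation_tally": {
                    "n_significant": tally.n_significant,
                    "n_negative": tally.n_negative,
                    "n_positive": tally.n_positive,
                },
            },
            outdir,
        )
    return manifest
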