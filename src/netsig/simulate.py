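"""Synthetic cohorts with planted ground truth.

The generator emulates the statistical structure of a two-condition
(growth-hormone deficiency, Turner syndrome) pharmacogenomic study of
response to recombinant human growth hormone: blood expression profiles at
baseline, five yearly height-velocity endpoints that decline over time,
clinical covariates explaining roughly half of response variance, a planted
interactome module whose members carry condition-specific
expression-response effects, LD-blocked candidate-gene genotypes, and
methylation skewed toward hypermethylation at low response.

The response model is a latent-component decomposition

    hv_year = mu_year + sd_year * (sqrt(r2_clin) * z_clin
                                   + sqrt(r2_bio) * z_bio
                                   + sqrt(1 - r2_clin - r2_bio) * eps_year)

with ``z_clin`` a standardized linear combination of the clinical
covariates, ``z_bio`` a latent biological component that planted genes load
on, and the three components orthogonalized in-sample so the requested
variance shares are realized exactly before truncation at zero.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import (
    CONDITIONS,
    N_YEARS,
    CohortPhenotype,
    ExpressionMatrix,
    GenotypeMatrix,
    MethylationMatrix,
    SyntheticTruth,
    ValidationError,
)

__all__ = [
    "generate_interactome",
    "default_truth",
    "generate_cohort",
    "generate_genotypes",
    "generate_methylation",
]

# Yearly height-velocity means/SDs (cm/year), first year largest with a
# decline to maintenance growth; values follow the published cohort pattern.
HV_MEANS = {"GHD": (8.9, 7.4, 6.6, 6.1, 5.1), "TS": (7.6, 6.0, 5.3, 4.7, 3.7)}
HV_SDS = {"GHD": (2.1, 1.6, 2.0, 2.3, 2.3), "TS": (1.4, 1.1, 1.5, 1.8, 1.6)}
# Fraction of samples still observed at each year (declining follow-up).
OBS_FRAC = {"GHD": (1.0, 0.92, 0.92, 0.85, 0.75), "TS": (1.0, 0.72, 0.93, 0.95, 0.77)}
# Fractions of response variance explained by clinical covariates.
DEFAULT_CLINICAL_R2 = {"GHD": 0.61, "TS": 0.46}
DEFAULT_BIO_R2 = 0.25
# Share of methylation-response associations that are negative
# (hypermethylated at low response).
DEFAULT_NEG_METHYL_FRACTION = 425.0 / 497.0

#: weights of the clinical covariates in the response model (younger, heavier
#: at birth, further from target height and -- in GHD -- more severe GH
#: deficiency respond better)
CLINICAL_WEIGHTS = {
    "age": -0.40,
    "weight_sds": 0.30,
    "birthweight_sds": 0.20,
    "dth_sds": -0.35,
    "peak_gh": -0.35,  # GHD only
}

EXPR_NOISE_SD = 0.5


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _orthogonalize(x: np.ndarray, others: list[np.ndarray]) -> np.ndarray:
    """Residualize ``x`` on ``others`` (plus intercept) and re-standardize."""
    if others:
        design = np.column_stack([np.ones_like(x)] + others)
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        x = x - design @ beta
    else:
        x = x - x.mean()
    return _standardize(x)


def generate_interactome(
    n_genes: int,
    module_sizes: Iterable[int],
    p_in: float,
    p_out: float,
    seed: int,
    attach_edges: int = 2,
) -> tuple[nx.Graph, dict[str, int]]:
    """Planted-partition gene graph with preferentially attached background.

    Module nodes draw within-module edges with probability ``p_in`` and
    between-module edges with ``p_out``; the remaining background nodes are
    attached one by one with ``attach_edges`` edges each, preferentially to
    high-degree nodes.  Returns the graph and the membership truth
    (gene -> module index, -1 for background).
    """
    module_sizes = list(module_sizes)
    if not 0 <= p_out < p_in <= 1:
        raise ValidationError(f"need 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    if any(s <= 0 for s in module_sizes):
        raise ValidationError("module sizes must be positive")
    if sum(module_sizes) > n_genes:
        raise ValidationError("sum of module sizes exceeds n_genes")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    membership: dict[str, int] = {}
    graph = nx.Graph()
    graph.add_nodes_from(genes[: sum(module_sizes)])

    offset = 0
    blocks: list[list[str]] = []
    for m, size in enumerate(module_sizes):
        block = genes[offset : offset + size]
        blocks.append(block)
        for g in block:
            membership[g] = m
        offset += size

    # within/between module edges from the planted partition
    module_nodes = genes[:offset]
    for i in range(len(module_nodes)):
        for j in range(i + 1, len(module_nodes)):
            same = membership[module_nodes[i]] == membership[module_nodes[j]]
            p = p_in if same else p_out
            if p > 0 and rng.random() < p:
                graph.add_edge(module_nodes[i], module_nodes[j])

    # background nodes attach preferentially (degree + 1 weighting, via the
    # standard repeated-endpoint urn so attachment stays O(n * attach_edges))
    urn: list[str] = list(module_nodes)
    for u, v in graph.edges:
        urn.append(u)
        urn.append(v)
    for g in genes[offset:]:
        membership[g] = -1
        graph.add_node(g)
        targets: set[str] = set()
        if urn:
            k = min(attach_edges, graph.number_of_nodes() - 1)
            guard = 0
            while len(targets) < k and guard < 50 * (k + 1):
                targets.add(urn[int(rng.integers(0, len(urn)))])
                guard += 1
        for t in sorted(targets):  # sorted: urn content independent of set order
            graph.add_edge(g, t)
            urn.append(t)
        urn.extend([g] * (len(targets) + 1))
    return graph, membership


def default_truth(
    planted_genes: Iterable[str],
    seed: int,
    clinical_r2: Mapping[str, float] | None = None,
    bio_r2: float | Mapping[str, float] = DEFAULT_BIO_R2,
    neg_methyl_fraction: float = DEFAULT_NEG_METHYL_FRACTION,
    effect_range: tuple[float, float] = (0.6, 1.2),
    dropout: float = 0.3,
    null: bool = False,
) -> SyntheticTruth:
    """Draw per-condition effects for the planted module genes.

    Each planted gene carries a shared sign and condition-specific magnitudes;
    with probability ``dropout`` a gene's effect is silenced in one condition
    (never both), so the per-gene significant sets of the two conditions
    overlap only weakly while the module itself is shared.
    """
    rng = np.random.default_rng(seed)
    planted = sorted(planted_genes)
    clinical_r2 = dict(clinical_r2 or DEFAULT_CLINICAL_R2)
    if not isinstance(bio_r2, Mapping):
        bio_r2 = {c: float(bio_r2) for c in CONDITIONS}
    effects: dict[str, dict[str, float]] = {}
    lo, hi = effect_range
    for g in planted:
        if null:
            effects[g] = {c: 0.0 for c in CONDITIONS}
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        while True:
            on = [rng.random() >= dropout for _ in CONDITIONS]
            if any(on):
                break
        effects[g] = {
            c: (sign * rng.uniform(lo, hi) if keep else 0.0)
            for c, keep in zip(CONDITIONS, on)
        }
    return SyntheticTruth(
        planted_module_genes=frozenset(planted),
        per_condition_effect=effects,
        clinical_r2=clinical_r2,
        neg_methyl_fraction=neg_methyl_fraction,
        rng_seed=seed,
        bio_r2=dict(bio_r2),
    )


def _simulate_condition_phenotype(
    condition: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    ids = [f"{condition}{i + 1:03d}" for i in range(n)]
    if condition == "TS":
        sex = np.array(["F"] * n)
    else:
        sex = np.where(rng.random(n) < 0.64, "M", "F")
    age = rng.uniform(6.0, 12.0, n)
    table = pd.DataFrame(
        {
            "condition": condition,
            "sex": sex,
            "age": age,
            "bmi_sds": rng.normal(-0.2 if condition == "GHD" else 0.4, 1.0, n),
            "weight_sds": rng.normal(-1.5, 1.0, n),
            "birthweight_sds": rng.normal(-0.5, 1.0, n),
            "dth_sds": rng.normal(-1.5, 0.8, n),
            "peak_gh": (
                np.round(rng.lognormal(np.log(3.9), 0.5, n), 3)
                if condition == "GHD"
                else np.full(n, np.nan)
            ),
            "batch": rng.choice(["B1", "B2", "B3"], n),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    # Tanner progression: deterministic threshold on age plus a per-child
    # offset, made non-decreasing by construction.
    offs = rng.normal(0.0, 0.8, n)
    stages = np.empty((n, N_YEARS), dtype=int)
    for y in range(1, N_YEARS + 1):
        raw = 1 + np.floor((age + y - 10.5 + offs) / 1.5)
        stages[:, y - 1] = np.clip(raw, 1, 5).astype(int)
    stages = np.maximum.accumulate(stages, axis=1)
    for y in range(1, N_YEARS + 1):
        table[f"tanner{y}"] = stages[:, y - 1]
    return table


def _clinical_component(table: pd.DataFrame, condition: str) -> np.ndarray:
    z = np.zeros(len(table))
    for col, w in CLINICAL_WEIGHTS.items():
        if col == "peak_gh" and condition != "GHD":
            continue
        z = z + w * _standardize(table[col].to_numpy(dtype=float))
    return _standardize(z)


def generate_cohort(
    truth: SyntheticTruth,
    interactome: nx.Graph,
    n_per_condition: Mapping[str, int],
    n_genes_expressed: int,
    seed: int,
) -> tuple[ExpressionMatrix, CohortPhenotype]:
    """Expression matrix and phenotype table for both conditions.

    The expressed gene set is drawn from the interactome nodes and always
    contains the planted module.  Planted genes load the per-condition effect
    times the latent biological response component on top of baseline,
    batch/age/BMI/sex covariate effects and Gaussian noise; all other genes
    carry covariate effects and noise only.
    """
    rng = np.random.default_rng(seed)
    for cond, n in n_per_condition.items():
        if n < 8:
            raise ValidationError(
                f"n_per_condition[{cond}] = {n} < 8: quartile machinery degenerate"
            )
    planted = sorted(truth.planted_module_genes)
    nodes = sorted(interactome.nodes)
    missing = set(planted) - set(nodes)
    if missing:
        raise ValidationError(f"planted genes absent from interactome: {sorted(missing)[:5]}")
    if n_genes_expressed < len(planted):
        raise ValidationError("n_genes_expressed smaller than planted module")
    others = [g for g in nodes if g not in truth.planted_module_genes]
    n_extra = min(n_genes_expressed - len(planted), len(others))
    chosen = list(rng.choice(others, size=n_extra, replace=False)) if n_extra else []
    genes = sorted(planted + chosen)
    if len(genes) < n_genes_expressed:  # pad with off-interactome probes
        pad = [f"OFFNET{i:05d}" for i in range(n_genes_expressed - len(genes))]
        genes = sorted(genes + pad)

    tables = []
    z_bios = {}
    for cond in CONDITIONS:
        n = int(n_per_condition.get(cond, 0))
        if n == 0:
            continue
        table = _simulate_condition_phenotype(cond, n, rng)
        z_clin = _clinical_component(table, cond)
        z_bio = _orthogonalize(rng.normal(size=n), [z_clin])
        r2c = float(truth.clinical_r2.get(cond, 0.5))
        r2b = min(float(truth.bio_r2.get(cond, DEFAULT_BIO_R2)), 1.0 - r2c)
        for y in range(1, N_YEARS + 1):
            eps = _orthogonalize(rng.normal(size=n), [z_clin, z_bio])
            lin = (
                np.sqrt(r2c) * z_clin
                + np.sqrt(r2b) * z_bio
                + np.sqrt(max(0.0, 1.0 - r2c - r2b)) * eps
            )
            hv = HV_MEANS[cond][y - 1] + HV_SDS[cond][y - 1] * lin
            hv = np.maximum(hv, 0.0)
            if y > 1:  # declining follow-up: later years partially missing
                keep = rng.random(n) < OBS_FRAC[cond][y - 1]
                hv = np.where(keep, hv, np.nan)
            table[f"hv{y}"] = np.round(hv, 4)
        tables.append(table)
        z_bios[cond] = pd.Series(z_bio, index=table.index)

    pheno = pd.concat(tables)
    phenotype = CohortPhenotype(pheno)

    # expression: baseline + covariate effects + planted signal + noise
    n_samples = len(pheno)
    gene_index = pd.Index(genes, name="gene_id")
    base = rng.normal(7.0, 1.0, len(genes))
    batches = sorted(pheno["batch"].unique())
    batch_eff = rng.normal(0.0, 0.15, (len(genes), len(batches)))
    batch_idx = pheno["batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()
    age_slope = rng.normal(0.0, 0.02, len(genes))
    bmi_slope = rng.normal(0.0, 0.02, len(genes))
    sex_eff = rng.normal(0.0, 0.05, len(genes))
    age_std = _standardize(pheno["age"].to_numpy(dtype=float))
    bmi_std = _standardize(pheno["bmi_sds"].to_numpy(dtype=float))
    is_male = (pheno["sex"] == "M").to_numpy(dtype=float)

    values = (
        base[:, None]
        + batch_eff[:, batch_idx]
        + age_slope[:, None] * age_std[None, :]
        + bmi_slope[:, None] * bmi_std[None, :]
        + sex_eff[:, None] * is_male[None, :]
        + rng.normal(0.0, EXPR_NOISE_SD, (len(genes), n_samples))
    )
    expr = pd.DataFrame(values, index=gene_index, columns=pheno.index)
    for g in planted:
        for cond, zb in z_bios.items():
            e = float(truth.per_condition_effect.get(g, {}).get(cond, 0.0))
            if e != 0.0:
                expr.loc[g, zb.index] += e * EXPR_NOISE_SD * zb.to_numpy()
    return ExpressionMatrix(expr), phenotype


def generate_genotypes(
    n_markers: int,
    n_blocks: int,
    phenotype: CohortPhenotype,
    assoc_markers: Mapping[str, float] | None,
    seed: int,
    n_genes_panel: int = 103,
    ld_copy_prob: float = 0.9,
    missing_rate: float = 0.01,
    x_gene_fraction: float = 0.08,
) -> GenotypeMatrix:
    """Candidate-gene genotype calls organized in LD blocks.

    Markers are distributed over a panel of genes; blocks are nested within
    genes and within-block calls are correlated through shared haplotypes.
    Markers listed in ``assoc_markers`` are drawn with allele probabilities
    tilted by the sample's standardized year-1 response.  Non-pseudoautosomal
    X markers in TS (45,X) and male GHD samples are hemizygous and emit only
    homozygote codes.
    """
    if n_blocks > n_markers:
        raise ValidationError("n_blocks exceeds n_markers")
    if n_blocks < 1 or n_markers < 1:
        raise ValidationError("n_markers and n_blocks must be positive")
    n_genes_panel = min(n_genes_panel, n_blocks)
    rng = np.random.default_rng(seed)
    markers = [f"rs{i + 1:06d}" for i in range(n_markers)]
    assoc = dict(assoc_markers or {})
    unknown = set(assoc) - set(markers)
    if unknown:
        raise ValidationError(f"effect on markers absent from the panel: {sorted(unknown)[:5]}")

    # nested assignment: markers -> blocks -> genes
    block_of_marker = np.sort(rng.integers(0, n_blocks, n_markers))
    # ensure every block non-empty by seeding one marker per block
    block_of_marker[:n_blocks] = np.arange(n_blocks)
    block_of_marker = np.sort(block_of_marker)
    gene_of_block = np.sort(rng.integers(0, n_genes_panel, n_blocks))
    gene_of_block[:n_genes_panel] = np.arange(n_genes_panel)
    gene_of_block = np.sort(gene_of_block)

    chroms = [str(c) for c in range(1, 23)] + ["X"]
    gene_chrom = {}
    for g in range(n_genes_panel):
        if rng.random() < x_gene_fraction:
            gene_chrom[g] = "X"
        else:
            gene_chrom[g] = chroms[int(rng.integers(0, 22))]

    pheno = phenotype.table
    samples = pheno.index
    n = len(samples)
    z_resp = _standardize(pheno["hv1"].to_numpy(dtype=float))
    hemizygous = (
        (pheno["condition"] == "TS") | ((pheno["condition"] == "GHD") & (pheno["sex"] == "M"))
    ).to_numpy()

    block_freq = rng.uniform(0.15, 0.85, n_blocks)
    block_hap = rng.random((n_blocks, n, 2)) < block_freq[:, None, None]

    calls = np.empty((n_markers, n), dtype=object)
    meta_rows = []
    for m, marker in enumerate(markers):
        b = int(block_of_marker[m])
        g = int(gene_of_block[b])
        chrom = gene_chrom[g]
        par = bool(chrom == "X" and rng.random() < 0.1)
        meta_rows.append(
            {"gene": f"PANEL{g + 1:03d}", "chromosome": chrom,
             "ld_block_id": f"LD{b + 1:04d}", "pseudoautosomal": par}
        )
        p = block_freq[b]
        if marker in assoc:
            p_i = expit(logit(np.clip(p, 1e-6, 1 - 1e-6)) + assoc[marker] * z_resp)
            hap = rng.random((n, 2)) < p_i[:, None]
        else:
            copy = rng.random((n, 2)) < ld_copy_prob
            fresh = rng.random((n, 2)) < p
            hap = np.where(copy, block_hap[b], fresh)
        dose = hap.sum(axis=1)
        if chrom == "X" and not par:
            # hemizygous samples carry a single allele, duplicated
            dose = np.where(hemizygous, 2 * hap[:, 0].astype(int), dose)
        codes = np.array(["AA", "AB", "BB"], dtype=object)[dose]
        miss = rng.random(n) < missing_rate
        codes[miss] = "NA"
        calls[m] = codes

    calls_df = pd.DataFrame(calls, index=pd.Index(markers, name="marker_id"), columns=samples)
    meta = pd.DataFrame(meta_rows, index=calls_df.index)
    geno = GenotypeMatrix(calls_df, meta)
    geno.validate_x_homozygosity(phenotype)
    return geno


def generate_methylation(
    truth: SyntheticTruth,
    phenotype: CohortPhenotype,
    n_genes: int,
    seed: int,
    slope_range: tuple[float, float] = (1.5, 3.0),
    noise_sd: float = 0.5,
) -> MethylationMatrix:
    """Gene-level beta values with response-associated planted genes.

    Betas are logistic transforms of a Gaussian latent; planted genes get a
    response slope whose sign is negative with probability
    ``truth.neg_methyl_fraction`` (hypermethylation at low response).
    """
    pheno = phenotype.table
    if len(pheno) < 2:
        raise ValidationError("methylation generation needs >= 2 samples")
    planted = sorted(truth.planted_module_genes)
    if n_genes < len(planted):
        raise ValidationError("n_genes smaller than the planted gene set")
    rng = np.random.default_rng(seed)
    filler = [f"MGENE{i:05d}" for i in range(n_genes - len(planted))]
    genes = planted + filler
    n = len(pheno)
    z_resp = _standardize(pheno["hv1"].to_numpy(dtype=float))

    base = rng.normal(-0.5, 1.2, len(genes))
    lo, hi = slope_range
    slopes = np.zeros(len(genes))
    mags = rng.uniform(lo, hi, len(planted))
    signs = np.where(rng.random(len(planted)) < truth.neg_methyl_fraction, -1.0, 1.0)
    slopes[: len(planted)] = mags * signs
    latent = (
        base[:, None]
        + slopes[:, None] * z_resp[None, :] * noise_sd
        + rng.normal(0.0, noise_sd, (len(genes), n))
    )
    beta = expit(latent)
    df = pd.DataFrame(beta, index=pd.Index(genes, name="gene_id"), columns=pheno.index)
    return MethylationMatrix(df)
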