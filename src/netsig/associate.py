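"""Association scans: covariate-residualized rank regression and genotype tests.

The expression-response scan removes clinical/technical covariates from both
the expression values and the response by ordinary least squares, then tests
each gene by simple linear regression on midrank-transformed residuals.  The
resulting nested-model F test with one numerator degree of freedom is the
Spearman-correlation test in disguise; for very small cohorts an exact
permutation p-value over all response orderings is used instead.

Genotype-response association uses the Kruskal-Wallis rank-sum test under
genotypic, dominant and recessive genetic models with LD-block-aware
Bonferroni and Benjamini-Hochberg adjustments.
"""

from __future__ import annotations

from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    ExpressionMatrix,
    GenotypeMatrix,
    ValidationError,
)

__all__ = [
    "build_design",
    "residualize_covariates",
    "residualize_response",
    "rank_regression_scan",
    "kruskal_wallis_genetic",
    "adjust_ld_bonferroni",
    "adjust_fdr_bh",
    "variance_filter",
]

GENETIC_MODELS = ("genotypic", "dominant", "recessive")
#: exact permutation test used at or below this sample size
EXACT_N_MAX = 8


def _as_frame(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, ExpressionMatrix) else matrix


def build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Design matrix with intercept; nominal columns expanded to indicators.

    Collinear columns are pruned (keeping the earliest); if the design is
    still rank-deficient the aliased columns are named in the error.
    """
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            if s.isna().any():
                raise ValidationError(f"covariate {col!r} has missing values")
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.extend(dummies[c] for c in dummies.columns)
    design = pd.concat(parts, axis=1)

    # prune exactly collinear columns greedily, earliest kept
    kept: list[str] = []
    dropped: list[str] = []
    arr = design.to_numpy(dtype=float)
    for j, col in enumerate(design.columns):
        trial = arr[:, [design.columns.get_loc(c) for c in kept] + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(col)
        else:
            dropped.append(col)
    pruned = design[kept]
    if np.linalg.matrix_rank(pruned.to_numpy(dtype=float)) < len(kept):
        raise ValidationError(f"rank-deficient design; aliased columns: {dropped or kept}")
    return pruned


def _residualize(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of each row of ``values`` on ``design`` columns."""
    beta, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    return values - (design @ beta).T


def residualize_covariates(
    matrix: ExpressionMatrix | pd.DataFrame, covariates: pd.DataFrame | None
) -> ExpressionMatrix:
    """Per-gene OLS residuals on the covariate design (intercept included).

    With a single nominal factor this is exactly within-group mean-centring;
    with no covariates it reduces to mean-centring each gene.
    """
    data = _as_frame(matrix)
    if covariates is None or covariates.shape[1] == 0:
        design = pd.DataFrame({"intercept": 1.0}, index=data.columns)
    else:
        covariates = covariates.loc[data.columns]
        design = build_design(covariates)
    resid = _residualize(data.to_numpy(dtype=float), design.to_numpy(dtype=float))
    return ExpressionMatrix(pd.DataFrame(resid, index=data.index, columns=data.columns))


def residualize_response(response: pd.Series, covariates: pd.DataFrame | None) -> pd.Series:
    frame = pd.DataFrame([response.to_numpy(dtype=float)], columns=response.index)
    out = residualize_covariates(frame, covariates)
    return pd.Series(out.data.to_numpy()[0], index=response.index, name=response.name)


def _exact_spearman_p(gene_ranks: np.ndarray, resp_ranks: np.ndarray) -> np.ndarray:
    """Two-sided exact permutation p of the rank correlation, per gene row."""
    n = resp_ranks.size
    perms = np.array(list(permutations(range(n))))
    perm_resp = resp_ranks[perms]  # (n!, n)
    gene_c = gene_ranks - gene_ranks.mean(axis=1, keepdims=True)
    resp_c = perm_resp - perm_resp.mean(axis=1, keepdims=True)
    num = resp_c @ gene_c.T  # (n!, genes)
    gnorm = np.sqrt((gene_c**2).sum(axis=1))
    rnorm = np.sqrt((resp_c**2).sum(axis=1))
    denom = rnorm[:, None] * gnorm[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    obs = np.abs(r[0])
    return (np.abs(r) >= obs[None, :] - 1e-12).mean(axis=0)


def rank_regression_scan(
    matrix: ExpressionMatrix | pd.DataFrame,
    response: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.01,
    adjust_response: bool = True,
    exact: bool | None = None,
) -> pd.DataFrame:
    """Per-gene rank regression of expression on a response endpoint.

    Expression (and, by default, the response) is residualized on the
    covariates first; both sides are then midrank-transformed and each gene
    is tested by the 1-df nested-model F statistic of the regression of
    expression ranks on response ranks.  ``exact`` switches to the exact
    permutation distribution (automatic for n <= 8).

    Returns an association table with columns feature_id, statistic, sign,
    p, p_adj (Benjamini-Hochberg), method, model, flagged, degenerate.
    """
    data = _as_frame(matrix)
    resp = response.dropna()
    samples = [s for s in data.columns if s in resp.index]
    if len(samples) < 8 and not (exact or len(samples) >= 4):
        raise ValidationError(f"scan needs n >= 8 (or exact mode with n >= 4), got {len(samples)}")
    data = data[samples]
    resp = resp.loc[samples]
    cov = covariates.loc[samples] if covariates is not None else None

    n_cov = 0
    if cov is not None and cov.shape[1] > 0:
        n_cov = build_design(cov).shape[1] - 1  # intercept not counted
    resid_x = residualize_covariates(data, cov).data.to_numpy()
    resid_y = (
        residualize_response(resp, cov).to_numpy()
        if adjust_response
        else resp.to_numpy(dtype=float)
    )
    n = len(samples)
    degenerate = resid_x.std(axis=1) <= 1e-12

    rank_x = np.apply_along_axis(stats.rankdata, 1, resid_x)
    rank_y = stats.rankdata(resid_y)
    xc = rank_x - rank_x.mean(axis=1, keepdims=True)
    yc = rank_y - rank_y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc @ yc) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)

    use_exact = exact if exact is not None else n <= EXACT_N_MAX
    if use_exact:
        if n > 9:
            raise ValidationError("exact permutation test limited to n <= 9")
        p = _exact_spearman_p(rank_x, rank_y)
    else:
        # residual df accounts for the eliminated covariate columns
        df2 = n - 2 - n_cov
        if df2 < 1:
            raise ValidationError("not enough residual degrees of freedom")
        with np.errstate(invalid="ignore", divide="ignore"):
            f_stat = r**2 * df2 / (1.0 - r**2)
        f_stat = np.where(np.isclose(np.abs(r), 1.0), np.inf, f_stat)
        p = stats.f.sf(f_stat, 1, df2)
    p = np.where(degenerate, 1.0, p)
    r = np.where(degenerate, 0.0, r)

    table = pd.DataFrame(
        {
            "feature_id": data.index,
            "statistic": r,
            "sign": np.where(r >= 0, "+", "-"),
            "p": p,
            "method": "rank_regression",
            "model": "none",
            "degenerate": degenerate,
        }
    )
    table = adjust_fdr_bh(table)
    table["flagged"] = table["p"] < alpha
    return table


def _kw_groups(calls: pd.Series, model: str) -> Mapping[str, pd.Index]:
    present = calls[calls != "NA"]
    if model == "genotypic":
        keys = {"AA": ("AA",), "AB": ("AB",), "BB": ("BB",)}
    elif model == "dominant":
        keys = {"AA": ("AA",), "AB+BB": ("AB", "BB")}
    elif model == "recessive":
        keys = {"AA+AB": ("AA", "AB"), "BB": ("BB",)}
    else:
        raise ValidationError(f"unknown genetic model {model!r}")
    groups = {}
    for name, codes in keys.items():
        idx = present.index[present.isin(codes)]
        if len(idx):
            groups[name] = idx
    return groups


def kruskal_wallis_genetic(
    genotypes: GenotypeMatrix,
    response: pd.Series,
    model: str = "genotypic",
) -> pd.DataFrame:
    """Kruskal-Wallis test of response across genotype groups, per marker.

    ``model`` is one of genotypic (AA/AB/BB), dominant (AA vs AB+BB) or
    recessive (AA+AB vs BB).  Markers whose grouping collapses to fewer than
    two non-empty groups are skipped with the reason recorded.  The sign
    column encodes whether response increases (+) or decreases (-) with B
    dosage (difference of extreme group means).
    """
    if model not in GENETIC_MODELS:
        raise ValidationError(f"model must be one of {GENETIC_MODELS}")
    resp = response.dropna()
    samples = [s for s in genotypes.sample_ids if s in resp.index]
    resp = resp.loc[samples]
    rows = []
    for marker in genotypes.marker_ids:
        calls = genotypes.calls.loc[marker, samples]
        groups = _kw_groups(calls, model)
        if len(groups) < 2:
            rows.append(
                {"feature_id": marker, "statistic": np.nan, "sign": "+", "p": np.nan,
                 "method": "kruskal_wallis", "model": model, "degenerate": True,
                 "skip_reason": f"only {len(groups)} non-empty group(s)"}
            )
            continue
        vals = [resp.loc[idx].to_numpy(dtype=float) for idx in groups.values()]
        pooled = np.concatenate(vals)
        if np.ptp(pooled) == 0:
            h_stat, p = 0.0, 1.0
        else:
            h_stat, p = stats.kruskal(*vals)
        direction = float(np.mean(vals[-1]) - np.mean(vals[0]))  # last group is B-heavy
        rows.append(
            {"feature_id": marker, "statistic": float(h_stat),
             "sign": "+" if direction >= 0 else "-", "p": float(p),
             "method": "kruskal_wallis", "model": model, "degenerate": False,
             "skip_reason": ""}
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    ok = table["p"].notna()
    if ok.any():
        table.loc[ok, "p_adj"] = multipletests(table.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]
    return table


def adjust_ld_bonferroni(
    table: pd.DataFrame,
    gene_blocks: Mapping[str, int],
    marker_gene: Mapping[str, str],
    total_blocks: int,
) -> pd.DataFrame:
    """Bonferroni adjustment at two LD-aware scales.

    Adds ``p_adj_gene`` (raw p times the number of LD blocks in the marker's
    gene) and ``p_adj_genome`` (raw p times the total number of LD blocks
    across all genes), both clipped at 1.
    """
    if total_blocks < 1:
        raise ValidationError("total_blocks must be >= 1")
    out = table.copy()
    counts = []
    for marker in out["feature_id"]:
        gene = marker_gene.get(marker)
        if gene is None or gene not in gene_blocks:
            raise ValidationError(f"missing LD-block annotation for marker {marker!r}")
        b = int(gene_blocks[gene])
        if b < 1:
            raise ValidationError(f"gene {gene!r} has block count {b} < 1")
        counts.append(b)
    out["p_adj_gene"] = np.minimum(out["p"].to_numpy(dtype=float) * np.asarray(counts), 1.0)
    out["p_adj_genome"] = np.minimum(out["p"].to_numpy(dtype=float) * total_blocks, 1.0)
    return out


def adjust_fdr_bh(table: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjusted p-values in column ``p_adj``."""
    out = table.copy()
    p = out["p"].to_numpy(dtype=float)
    if len(p) == 0:
        out["p_adj"] = p
        return out
    out["p_adj"] = multipletests(p, method="fdr_bh")[1]
    return out


def _projection_score(values: np.ndarray, n_components: int, rng: np.random.Generator,
                      n_null: int = 3) -> float:
    """Variance captured by leading PCs minus a permutation-null baseline."""
    centred = values - values.mean(axis=1, keepdims=True)
    total = (centred**2).sum()
    if total == 0:
        return 0.0
    k = min(n_components, min(centred.shape) - 1)
    s = np.linalg.svd(centred, compute_uv=False)
    observed = (s[:k] ** 2).sum() / total
    null_vals = []
    for _ in range(n_null):
        perm = np.array([rng.permutation(row) for row in centred])
        perm -= perm.mean(axis=1, keepdims=True)
        sn = np.linalg.svd(perm, compute_uv=False)
        null_vals.append((sn[:k] ** 2).sum() / (perm**2).sum())
    return observed - float(np.mean(null_vals))


def variance_filter(
    matrix: ExpressionMatrix | pd.DataFrame,
    n_keep: int | None = None,
    n_components: int = 2,
    seed: int = 0,
    grid: Sequence[int] | None = None,
) -> ExpressionMatrix:
    """Keep the highest-variance genes.

    Fixed-count mode (``n_keep``) retains exactly ``n_keep`` genes.  The
    score-based mode sweeps candidate subset sizes and keeps the subset
    maximizing a projection score: the variance fraction captured by the
    leading principal components in excess of a per-gene permutation null.
    """
    data = _as_frame(matrix)
    variances = data.var(axis=1)
    order = variances.sort_values(ascending=False, kind="mergesort").index
    if n_keep is not None:
        if n_keep <= 0:
            raise ValidationError("n_keep must be positive")
        if n_keep > len(order):
            raise ValidationError("n_keep exceeds gene count")
        keep = order[:n_keep]
    else:
        rng = np.random.default_rng(seed)
        if grid is None:
            g = len(order)
            grid = sorted({max(2, g // 32), g // 16, g // 8, g // 4, g // 2, g})
        best_score, keep = -np.inf, order
        for size in grid:
            cand = order[:size]
            score = _projection_score(data.loc[cand].to_numpy(dtype=float),
                                      n_components, rng)
            if score > best_score:
                best_score, keep = score, cand
    sub = data.loc[keep.sort_values()]
    if isinstance(matrix, ExpressionMatrix):
        return type(matrix)(sub)
    return ExpressionMatrix(sub)
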