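"""Quartile classification of growth response.

Implements the supervised layer of the pipeline: quartile class labels,
SMOTE rebalancing, a bagged random forest with honest out-of-bag (OOB)
error and AUC (SMOTE is applied inside each bootstrap, never to the
out-of-bag samples, so the OOB estimate stays leakage-free), BORUTA
shadow-feature confirmation, PLS-DA and DAPC ordinations, and the
comparison of clinical-phenotype-only models against clinical + transcriptome
models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

from .datatypes import ValidationError

__all__ = [
    "quartile_labels",
    "binary_task",
    "smote_oversample",
    "rf_classify_oob",
    "boruta_select",
    "pls_da_fit",
    "dapc_fit",
    "compare_phenotype_models",
    "paired_uplift_test",
    "ResponseClassLabels",
    "ClassificationReport",
]

log = logging.getLogger(__name__)

DEFAULT_TREES = 1000
DEFAULT_SMOTE_K = 5
DEFAULT_BORUTA_ITER = 100


@dataclass
class ResponseClassLabels:
    labels: pd.Series  # sample -> low | mid | high
    endpoint: str
    quartile_size: int

    def task(self, which: str) -> pd.Series:
        return binary_task(self.labels, which)


@dataclass
class BaggedForest:
    """The fitted tree ensemble, for predicting independent samples."""

    trees: list = field(repr=False, default_factory=list)

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        acc = np.zeros((len(X), 2))
        for tree in self.trees:
            proba = tree.predict_proba(X)
            cols = {c: i for i, c in enumerate(tree.classes_)}
            for cls in (0, 1):
                if cls in cols:
                    acc[:, cls] += proba[:, cols[cls]]
        return acc / len(self.trees)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass
class ClassificationReport:
    auc: float
    auc_ci: tuple[float, float]
    oob_error: float
    importance: pd.Series
    n_trees: int
    seed: int
    oob_scores: pd.Series = field(repr=False, default=None)
    boruta_status: pd.Series | None = None
    model: BaggedForest | None = field(repr=False, default=None)


def quartile_labels(response: pd.Series, endpoint: str = "") -> ResponseClassLabels:
    """Low/mid/high classes from the response quartiles.

    The floor(n/4) smallest responses are ``low``, the floor(n/4) largest
    ``high``, the remainder ``mid``; boundary ties are broken by sample id so
    the labelling is deterministic.
    """
    resp = response.dropna()
    n = len(resp)
    if n < 8:
        raise ValidationError(f"quartile labelling needs n >= 8, got {n}")
    if not np.isfinite(resp.to_numpy(dtype=float)).all():
        raise ValidationError("non-finite response values")
    if resp.nunique() == 1:
        log.warning("all responses equal for %s; id-ordered quartile split", endpoint)
    k = n // 4
    order = resp.to_frame("v").assign(sid=resp.index.astype(str)) \
        .sort_values(["v", "sid"], kind="mergesort").index
    labels = pd.Series("mid", index=resp.index, name="class")
    labels.loc[order[:k]] = "low"
    labels.loc[order[n - k:]] = "high"
    return ResponseClassLabels(labels=labels, endpoint=endpoint, quartile_size=k)


def binary_task(labels: pd.Series, which: str) -> pd.Series:
    """One-vs-rest indicator for the low or high quartile task."""
    if which not in ("low", "high"):
        raise ValidationError("task must be 'low' or 'high'")
    return (labels == which).astype(int)


def smote_oversample(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    k: int = DEFAULT_SMOTE_K,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to balanced class counts.

    Each synthetic sample is x + u * (x_nn - x) with u ~ U(0, 1) and x_nn a
    random one of x's k nearest minority neighbours (Euclidean; k capped at
    minority - 1).  Originals are retained unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 1:
        raise ValidationError("k must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("SMOTE expects two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValidationError("minority class of 1 has no neighbour to interpolate")
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    Xm = X[y == minority]
    k_eff = min(k, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # first column is self
    base = rng.integers(0, n_min, n_new)
    pick = idx[base, rng.integers(1, k_eff + 1, n_new)]
    u = rng.random((n_new, 1))
    synth = Xm[base] + u * (Xm[pick] - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def _delong_ci(y: np.ndarray, scores: np.ndarray, level: float = 0.95):
    """AUC with a DeLong asymptotic confidence interval."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() / m - (m + 1) / 2.0) / n
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))


def rf_classify_oob(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    n_trees: int = DEFAULT_TREES,
    seed: int = 0,
    smote: bool = True,
    smote_k: int = DEFAULT_SMOTE_K,
    smote_scope: str = "bootstrap",
) -> ClassificationReport:
    """Bagged random forest with out-of-bag error, AUC and 95% CI.

    Trees are sklearn CARTs with sqrt(p) features per split grown on
    bootstrap resamples.  With ``smote_scope='bootstrap'`` (default) SMOTE
    rebalances each bootstrap sample only, so out-of-bag predictions never
    see synthetic points derived from the held-out sample itself;
    ``'global'`` mimics oversampling the whole data set before bagging
    (leaky, kept for comparison); ``'none'`` disables rebalancing.  The AUC
    and its DeLong 95% CI are computed from out-of-bag class-probability
    votes, feature importance is mean impurity decrease across trees.
    """
    feature_names = (
        list(X.columns) if isinstance(X, pd.DataFrame)
        else [f"f{i}" for i in range(np.asarray(X).shape[1])]
    )
    sample_index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("binary classification expected")
    if counts.min() < 2:
        raise ValidationError("each class needs at least 2 members")
    y01 = (y == classes[1]).astype(int)
    n, p = X.shape
    if not smote:
        smote_scope = "none"
    if smote_scope == "global":
        Xg, yg = smote_oversample(X, y01, k=smote_k, seed=seed)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    votes = np.zeros((n, 2))
    vote_counts = np.zeros(n)
    importance = np.zeros(p)
    trees = []
    for _ in range(n_trees):
        tree_seed = int(rng.integers(0, 2**31 - 1))
        trng = np.random.default_rng(tree_seed)
        for _retry in range(20):
            boot = trng.integers(0, n, n)
            if len(np.unique(y01[boot])) == 2:
                break
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if smote_scope == "bootstrap":
            n_min = np.bincount(y01[boot], minlength=2).min()
            if n_min >= 2:
                Xb, yb = smote_oversample(
                    X[boot], y01[boot], k=min(smote_k, n_min - 1),
                    seed=int(trng.integers(0, 2**31 - 1)),
                )
            else:  # pragma: no cover - guarded by the retry loop above
                Xb, yb = X[boot], y01[boot]
        elif smote_scope == "global":
            boot = trng.integers(0, len(yg), len(yg))
            if len(np.unique(yg[boot])) < 2:
                continue
            Xb, yb = Xg[boot], yg[boot]
            oob = np.setdiff1d(np.arange(n), boot[boot < n])
        else:
            Xb, yb = X[boot], y01[boot]
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(trng.integers(0, 2**31 - 1))
        ).fit(Xb, yb)
        trees.append(tree)
        importance += tree.feature_importances_
        if len(oob):
            proba = tree.predict_proba(X[oob])
            cols = {c: i for i, c in enumerate(tree.classes_)}
            for cls in (0, 1):
                if cls in cols:
                    votes[oob, cls] += proba[:, cols[cls]]
            vote_counts[oob] += 1

    seen = vote_counts > 0
    if not seen.all():
        log.warning("%d samples received no OOB votes", int((~seen).sum()))
    oob_prob = np.full(n, np.nan)
    oob_prob[seen] = votes[seen, 1] / vote_counts[seen]
    pred = (oob_prob[seen] >= 0.5).astype(int)
    oob_error = float(np.mean(pred != y01[seen]))
    auc, ci = _delong_ci(y01[seen], oob_prob[seen])
    return ClassificationReport(
        auc=auc,
        auc_ci=ci,
        oob_error=oob_error,
        importance=pd.Series(importance / n_trees, index=feature_names),
        n_trees=n_trees,
        seed=seed,
        oob_scores=pd.Series(oob_prob, index=sample_index),
        model=BaggedForest(trees=trees),
    )


def boruta_select(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    n_iter: int = DEFAULT_BORUTA_ITER,
    seed: int = 0,
    n_trees: int = 100,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """BORUTA all-relevant feature confirmation against shadow features.

    Every iteration appends a column-permuted shadow copy of each feature,
    fits a random forest, and scores a hit for each real feature whose
    importance exceeds the maximum shadow importance.  Hit counts are tested
    two-sided against Binomial(n_iter, 0.5) with Bonferroni correction over
    features: significantly above half are ``confirmed``, significantly
    below ``rejected``, the rest ``tentative``.
    """
    feature_names = (
        list(X.columns) if isinstance(X, pd.DataFrame)
        else [f"f{i}" for i in range(np.asarray(X).shape[1])]
    )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_iter < 10:
        raise ValidationError("n_iter must be >= 10")
    if min(np.bincount((y == np.unique(y)[1]).astype(int))) < 2:
        raise ValidationError("each class needs at least 2 samples")
    n, p = X.shape
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    hits = np.zeros(p, dtype=int)
    shadow_max, shadow_mean, shadow_min = [], [], []
    for _ in range(n_iter):
        shadow = np.column_stack([rng.permutation(X[:, j]) for j in range(p)])
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        ).fit(np.hstack([X, shadow]), y)
        imp = forest.feature_importances_
        real, sh = imp[:p], imp[p:]
        hits += real > sh.max()
        shadow_max.append(sh.max())
        shadow_mean.append(sh.mean())
        shadow_min.append(sh.min())
    pvals = np.array(
        [stats.binomtest(int(h), n_iter, 0.5).pvalue for h in hits]
    )
    adj = np.minimum(pvals * p, 1.0)
    status = np.where(
        (adj < alpha) & (hits > n_iter / 2), "confirmed",
        np.where((adj < alpha) & (hits < n_iter / 2), "rejected", "tentative"),
    )
    out = pd.DataFrame(
        {"feature": feature_names, "hits": hits, "n_iter": n_iter,
         "p": pvals, "p_adj": adj, "status": status}
    )
    out.attrs["shadow"] = {
        "max": float(np.mean(shadow_max)),
        "mean": float(np.mean(shadow_mean)),
        "min": float(np.mean(shadow_min)),
    }
    return out


@dataclass
class PLSDAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    weights: pd.DataFrame
    auc: float


def pls_da_fit(
    X: pd.DataFrame | np.ndarray, y: Sequence[int], n_components: int = 2
) -> PLSDAResult:
    """Partial least squares discriminant analysis (NIPALS) on a binary class.

    Fits PLS regression of the centred indicator on centred X; the first
    weight vector is proportional to X'y.  The reported AUC is that of the
    nearest-centroid rule in the latent score space.
    """
    names = (
        list(X.columns) if isinstance(X, pd.DataFrame)
        else [f"f{i}" for i in range(np.asarray(X).shape[1])]
    )
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValidationError("n_components exceeds min(n - 1, p)")
    if np.allclose(X.std(axis=0), 0):
        raise ValidationError("zero-variance feature matrix")
    pls = PLSRegression(n_components=n_components, scale=False).fit(X, y)
    scores = pls.x_scores_
    cent0 = scores[y == 0].mean(axis=0)
    cent1 = scores[y == 1].mean(axis=0)
    disc = np.linalg.norm(scores - cent0, axis=1) - np.linalg.norm(scores - cent1, axis=1)
    auc = float(roc_auc_score(y, disc)) if len(np.unique(y)) == 2 else np.nan
    comp = [f"comp{i + 1}" for i in range(n_components)]
    return PLSDAResult(
        scores=pd.DataFrame(scores, index=index, columns=comp),
        loadings=pd.DataFrame(pls.x_loadings_, index=names, columns=comp),
        weights=pd.DataFrame(pls.x_weights_, index=names, columns=comp),
        auc=auc,
    )


@dataclass
class DAPCResult:
    discriminants: pd.DataFrame
    predictions: pd.Series
    accuracy: float


def dapc_fit(
    X: pd.DataFrame | np.ndarray, groups: Sequence, n_pcs: int
) -> DAPCResult:
    """Discriminant analysis of principal components.

    PCA reduction to ``n_pcs`` followed by linear discriminant analysis on
    the retained scores; the discriminant function maximizes between-group
    relative to within-group variance.
    """
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if n_pcs >= len(X):
        raise ValidationError("n_pcs must be < n samples")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need >= 2 groups")
    if counts.min() < 2:
        raise ValidationError("a group with a single member cannot be discriminated")
    pca = PCA(n_components=n_pcs, svd_solver="full").fit(X)
    pcs = pca.transform(X)
    # drop numerically empty components: LDA would amplify their noise
    keep = pca.explained_variance_ratio_ > 1e-12
    if keep.any():
        pcs = pcs[:, keep]
    with np.errstate(invalid="ignore"):
        lda = LinearDiscriminantAnalysis().fit(pcs, groups)
        disc = lda.transform(pcs)
        pred = lda.predict(pcs)
    if disc.shape[1] == 0:  # degenerate: no between-group variance at all
        disc = np.zeros((len(pcs), 1))
    cols = [f"LD{i + 1}" for i in range(disc.shape[1])]
    return DAPCResult(
        discriminants=pd.DataFrame(disc, index=index, columns=cols),
        predictions=pd.Series(pred, index=index),
        accuracy=float(np.mean(pred == groups)),
    )


def compare_phenotype_models(
    clinical: pd.DataFrame,
    signature_expr: pd.DataFrame,
    y: pd.Series,
    n_trees: int = DEFAULT_TREES,
    seed: int = 0,
    smote: bool = True,
    smote_k: int = DEFAULT_SMOTE_K,
) -> tuple[ClassificationReport, ClassificationReport, dict[str, float]]:
    """Clinical-phenotype-only vs clinical + signature-transcriptome forests.

    ``clinical`` is samples x clinical features, ``signature_expr`` genes x
    samples.  Both forests share the seed and labels; the deltas dict holds
    the AUC gain and OOB-error drop of adding the transcriptome.
    """
    samples = list(y.index)
    if set(samples) - set(clinical.index):
        raise ValidationError("labelled samples missing from the clinical table")
    clin = clinical.loc[samples].astype(float)
    if signature_expr.shape[0] and set(samples) - set(signature_expr.columns):
        raise ValidationError("labelled samples missing from the expression matrix")
    rep_clin = rf_classify_oob(clin, y.loc[samples].to_numpy(), n_trees=n_trees,
                               seed=seed, smote=smote, smote_k=smote_k)
    expr_block = signature_expr[samples].T if signature_expr.shape[0] else \
        pd.DataFrame(index=samples)
    combined = pd.concat([clin, expr_block], axis=1)
    combined.columns = [str(c) for c in combined.columns]
    rep_comb = rf_classify_oob(combined, y.loc[samples].to_numpy(), n_trees=n_trees,
                               seed=seed, smote=smote, smote_k=smote_k)
    deltas = {
        "delta_auc": rep_comb.auc - rep_clin.auc,
        "delta_oob_error": rep_comb.oob_error - rep_clin.oob_error,
    }
    return rep_clin, rep_comb, deltas


def paired_uplift_test(
    auc_clinical: Iterable[float], auc_combined: Iterable[float]
) -> float:
    """Paired t-test p-value for combined > clinical AUC over endpoints."""
    a = np.asarray(list(auc_clinical), dtype=float)
    b = np.asarray(list(auc_combined), dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValidationError("need matched AUC lists of length >= 2")
    if np.allclose(a, b):
        return 1.0
    return float(stats.ttest_rel(b, a).pvalue)
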