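"""Typed containers shared by every pipeline stage.

Matrices are thin wrappers around a genes x samples :class:`pandas.DataFrame`
so that validation happens once, at construction, and downstream code can
rely on unique ids and finite values.  The interactome is a plain
:class:`networkx.Graph`; phenotype tables are a wrapped DataFrame indexed by
sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("GHD", "TS")
N_YEARS = 5
HV_COLS = tuple(f"hv{y}" for y in range(1, N_YEARS + 1))
TANNER_COLS = tuple(f"tanner{y}" for y in range(1, N_YEARS + 1))

#: clinical predictors used for the phenotype-only classifier
CLINICAL_FEATURES = ("age", "weight_sds", "birthweight_sds", "dth_sds")
#: extra clinical predictor available in GHD only
GHD_EXTRA_FEATURE = "peak_gh"

GENOTYPE_CODES = ("AA", "AB", "BB")
MISSING_CODE = "NA"


class ValidationError(ValueError):
    """A typed object failed its structural invariants."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")
    if (idx.astype(str).str.len() == 0).any():
        raise ValidationError(f"empty {what} id")


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression, genes as rows, samples as columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        self.data = self.data.astype(float)
        self.data.index.name = "gene_id"
        self.data.columns.name = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return type(self)(self.data.loc[:, list(samples)])

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return type(self)(self.data.loc[list(genes)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, type(self)) and self.data.equals(other.data)


@dataclass(eq=False)
class MethylationMatrix(ExpressionMatrix):
    """Gene- or probe-level beta values, constrained to [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.data.to_numpy()
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError("beta values must lie in [0, 1]")


@dataclass
class CohortPhenotype:
    """Per-sample clinical covariates, condition labels and yearly responses.

    ``table`` is indexed by sample id with columns: condition, sex, age,
    bmi_sds, weight_sds, birthweight_sds, dth_sds, peak_gh (NaN outside GHD),
    batch, tanner1..tanner5 and hv1..hv5 (later years may be NaN).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "sample")
        required = {"condition", "sex", "age", "bmi_sds", "weight_sds",
                    "birthweight_sds", "dth_sds", "peak_gh", "batch",
                    *TANNER_COLS, *HV_COLS}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
        bad_cond = set(t["condition"].unique()) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown condition labels: {sorted(bad_cond)}")
        if t["hv1"].isna().any():
            orphans = t.index[t["hv1"].isna()].tolist()[:5]
            raise ValidationError(f"year-1 height velocity missing for {orphans}")
        tanner = t[list(TANNER_COLS)].to_numpy(dtype=float)
        if (np.diff(tanner, axis=1) < 0).any():
            raise ValidationError("Tanner stage must be non-decreasing over years")
        is_ghd = t["condition"] == "GHD"
        if t.loc[is_ghd, "peak_gh"].isna().any():
            raise ValidationError("peak_gh missing for a GHD sample")
        if t.loc[~is_ghd, "peak_gh"].notna().any():
            raise ValidationError("peak_gh present for a non-GHD sample")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def condition(self, condition: str) -> "CohortPhenotype":
        sub = self.table[self.table["condition"] == condition]
        return CohortPhenotype(sub.copy())

    def hv(self, year: int) -> pd.Series:
        """Height velocity for ``year`` (1-5), NaN where unobserved."""
        return self.table[f"hv{year}"]

    def cumulative_growth(self) -> pd.Series:
        """Total cm grown over the observed years (sum of yearly velocities)."""
        return self.table[list(HV_COLS)].sum(axis=1, min_count=1)

    def clinical_features(self) -> pd.DataFrame:
        """Baseline clinical predictor block (adds peak GH for GHD samples)."""
        cols = list(CLINICAL_FEATURES)
        feats = self.table[cols].copy()
        if (self.table["condition"] == "GHD").all():
            feats[GHD_EXTRA_FEATURE] = self.table[GHD_EXTRA_FEATURE]
        return feats

    def __eq__(self, other: object) -> bool:
        return isinstance(other, type(self)) and self.table.equals(other.table)


@dataclass
class GenotypeMatrix:
    """Genotype calls (markers x samples) plus per-marker metadata.

    ``meta`` columns: gene, chromosome, ld_block_id, pseudoautosomal (bool).
    Calls are strings in {AA, AB, BB, NA}.
    """

    calls: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.calls.index, "marker")
        _check_unique(self.calls.columns, "sample")
        if not self.calls.index.equals(self.meta.index):
            raise ValidationError("calls and metadata marker ids differ")
        required = {"gene", "chromosome", "ld_block_id", "pseudoautosomal"}
        missing = required - set(self.meta.columns)
        if missing:
            raise ValidationError(f"marker metadata missing columns: {sorted(missing)}")
        allowed = set(GENOTYPE_CODES) | {MISSING_CODE}
        vals = self.calls.to_numpy(dtype=object)
        bad = set(np.unique(vals)) - allowed
        if bad:
            raise ValidationError(f"unknown genotype codes: {sorted(bad)}")
        if self.meta["ld_block_id"].isna().any():
            raise ValidationError("ld_block_id missing for some markers")
        self.calls.index.name = "marker_id"
        self.calls.columns.name = None
        self.meta.index.name = "marker_id"

    @property
    def marker_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.calls.columns

    def validate_x_homozygosity(self, phenotype: CohortPhenotype) -> None:
        """Non-pseudoautosomal X markers must be homozygous in TS and male GHD.

        TS karyotypes (45,X) and GHD boys carry a single X, so AB calls on
        non-pseudoautosomal X markers are impossible and flag corrupt input.
        """
        t = phenotype.table.loc[[s for s in self.sample_ids if s in phenotype.table.index]]
        hemi = t.index[(t["condition"] == "TS") | ((t["condition"] == "GHD") & (t["sex"] == "M"))]
        x = self.meta.index[(self.meta["chromosome"] == "X") & (~self.meta["pseudoautosomal"])]
        if len(hemi) == 0 or len(x) == 0:
            return
        block = self.calls.loc[x, hemi]
        if (block == "AB").any().any():
            where = block.stack()
            where = where[where == "AB"].index[0]
            raise ValidationError(
                f"heterozygous X call at marker {where[0]!r}, sample {where[1]!r} "
                "(hemizygous sample must be AA/BB)"
            )

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, type(self)) and self.calls.equals(other.calls)
                and self.meta.equals(other.meta))


@dataclass
class SyntheticTruth:
    """Ground truth planted by the simulator, kept for recovery scoring."""

    planted_module_genes: frozenset
    per_condition_effect: Mapping[str, Mapping[str, float]]  # gene -> condition -> effect
    clinical_r2: Mapping[str, float]
    neg_methyl_fraction: float
    rng_seed: int
    bio_r2: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.planted_module_genes = frozenset(self.planted_module_genes)
        for cond, r2 in self.clinical_r2.items():
            if not 0.0 <= r2 <= 1.0:
                raise ValidationError(f"clinical_r2[{cond}] = {r2} outside [0, 1]")
        if not 0.0 <= self.neg_methyl_fraction <= 1.0:
            raise ValidationError("neg_methyl_fraction outside [0, 1]")
        for gene, eff in self.per_condition_effect.items():
            for cond, e in eff.items():
                if not np.isfinite(e):
                    raise ValidationError(f"non-finite effect for {gene}/{cond}")
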