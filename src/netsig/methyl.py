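"""Gene-level methylation summarisation and response mapping.

Probe-level beta values are collapsed to a per-gene median; the
methylation-response association reuses the rank-regression scan (exact
permutation p-values at the very small sample sizes typical of methylation
sub-studies) and tallies the direction of significant associations --
hypermethylation at low response shows up as a negative share.  Signature
genes are mapped onto methylation by Spearman correlation against response
with an |r| threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import associate
from .datatypes import MethylationMatrix, ValidationError
from .signature import Signature

__all__ = [
    "summarize_gene_methylation",
    "methylation_response_scan",
    "map_signature_methylation",
    "DirectionTally",
]


@dataclass
class DirectionTally:
    n_significant: int
    n_negative: int
    n_positive: int

    @property
    def negative_share(self) -> float:
        return self.n_negative / self.n_significant if self.n_significant else np.nan


def summarize_gene_methylation(
    probes: MethylationMatrix | pd.DataFrame, probe_gene: Mapping[str, str]
) -> MethylationMatrix:
    """Median-based gene-level summary of probe beta values.

    Unmapped probes are dropped (count logged via the returned frame attrs);
    an even number of probes takes the mean of the two middle values.
    """
    data = probes.data if isinstance(probes, MethylationMatrix) else probes
    if not probe_gene:
        raise ValidationError("empty probe-to-gene mapping")
    genes = pd.Series({p: probe_gene.get(p) for p in data.index})
    mapped = genes.dropna()
    summary = data.loc[mapped.index].groupby(mapped).median()
    summary.index.name = "gene_id"
    out = MethylationMatrix(summary)
    out.data.attrs["n_unmapped_probes"] = int(len(data) - len(mapped))
    return out


def methylation_response_scan(
    meth: MethylationMatrix | pd.DataFrame,
    response: pd.Series,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, DirectionTally]:
    """Rank regression of gene-level methylation on response, with direction tally.

    No covariates are removed by default (methylation sub-studies are small);
    at n <= 8 the p-values come from the exact permutation distribution.
    Returns the association table and the tally of negative- vs
    positive-direction significant genes.
    """
    data = meth.data if isinstance(meth, MethylationMatrix) else meth
    n = response.dropna().size
    if n < 4:
        raise ValidationError(f"methylation scan needs n >= 4, got {n}")
    table = associate.rank_regression_scan(
        data, response, covariates=None, alpha=alpha, exact=n <= associate.EXACT_N_MAX
    )
    sig = table[table["flagged"]]
    tally = DirectionTally(
        n_significant=int(len(sig)),
        n_negative=int((sig["sign"] == "-").sum()),
        n_positive=int((sig["sign"] == "+").sum()),
    )
    return table, tally


def map_signature_methylation(
    signature: Signature | set[str],
    meth: MethylationMatrix | pd.DataFrame,
    response: pd.Series,
    r_threshold: float = 0.3,
) -> pd.DataFrame:
    """Spearman correlation of signature-gene methylation with response.

    Genes with |r| > ``r_threshold`` are classified as correlated (with
    sign); signature genes absent from the methylation matrix are reported
    as unmapped.
    """
    genes = sorted(signature.genes if isinstance(signature, Signature) else signature)
    data = meth.data if isinstance(meth, MethylationMatrix) else meth
    resp = response.dropna()
    samples = [s for s in data.columns if s in resp.index]
    rows = []
    for g in genes:
        if g not in data.index:
            rows.append({"gene": g, "r": np.nan, "correlated": False,
                         "direction": "unmapped", "mapped": False})
            continue
        r = stats.spearmanr(data.loc[g, samples], resp.loc[samples]).statistic
        correlated = bool(np.abs(r) > r_threshold)
        rows.append({
            "gene": g, "r": float(r), "correlated": correlated,
            "direction": ("negative" if r < 0 else "positive") if correlated else "none",
            "mapped": True,
        })
    return pd.DataFrame(rows, columns=["gene", "r", "correlated", "direction", "mapped"])
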