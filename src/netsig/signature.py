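"""Cross-condition core comparison and classification-signature selection.

The functional cores of the two conditions' network models are compared per
treatment year with an upper-tail hypergeometric overlap test; genes shared
by both cores enter the year's classification signature if rank regression
flagged them at p < 0.05 in either condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

__all__ = ["core_overlap_test", "select_signature", "yearwise_overlap_summary", "Signature"]

log = logging.getLogger(__name__)


@dataclass
class Signature:
    year: int
    genes: set[str]
    provenance: pd.DataFrame  # per shared gene: in_core_*, p_*, selected
    overlap_p: float
    shared: set[str] = field(default_factory=set)


def core_overlap_test(
    core_a: Iterable[str], core_b: Iterable[str], universe: int
) -> tuple[set[str], float]:
    """Shared genes and upper-tail hypergeometric overlap p-value.

    With a population of ``universe`` genes, |A| successes and |B| draws,
    p = P(X >= |A intersect B|).  Disjoint sets give p = 1 (P(X >= 0)).
    """
    a, b = set(core_a), set(core_b)
    shared = a & b
    if universe < len(a | b):
        raise ValidationError(
            f"universe {universe} smaller than |A union B| = {len(a | b)}"
        )
    p = float(stats.hypergeom.sf(len(shared) - 1, universe, len(a), len(b)))
    return shared, min(p, 1.0)


def _p_lookup(table: pd.DataFrame) -> Mapping[str, float]:
    return dict(zip(table["feature_id"], table["p"]))


def select_signature(
    shared: Iterable[str],
    assoc_ghd: pd.DataFrame,
    assoc_ts: pd.DataFrame,
    alpha: float = 0.05,
    year: int = 0,
    overlap_p: float = np.nan,
    core_ghd: Iterable[str] = (),
    core_ts: Iterable[str] = (),
) -> Signature:
    """Signature = shared-core genes associated (p < alpha) in either condition.

    Genes absent from both association tables are excluded with a logged
    reason; an empty result is allowed with a warning.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    p_ghd = _p_lookup(assoc_ghd)
    p_ts = _p_lookup(assoc_ts)
    core_ghd, core_ts = set(core_ghd), set(core_ts)
    rows = []
    selected = set()
    for g in sorted(set(shared)):
        pg, pt = p_ghd.get(g), p_ts.get(g)
        if pg is None and pt is None:
            log.warning("signature candidate %s absent from both association tables", g)
            continue
        keep = (pg is not None and pg < alpha) or (pt is not None and pt < alpha)
        if keep:
            selected.add(g)
        rows.append(
            {"gene": g, "in_core_ghd": g in core_ghd or not core_ghd,
             "in_core_ts": g in core_ts or not core_ts,
             "p_ghd": np.nan if pg is None else pg,
             "p_ts": np.nan if pt is None else pt, "selected": keep}
        )
    if not selected:
        log.warning("empty signature for year %s (no shared-core gene at p < %s)", year, alpha)
    prov = pd.DataFrame(rows, columns=["gene", "in_core_ghd", "in_core_ts",
                                       "p_ghd", "p_ts", "selected"])
    return Signature(year=year, genes=selected, provenance=prov,
                     overlap_p=overlap_p, shared=set(shared))


def yearwise_overlap_summary(
    cores: Mapping[str, Iterable[str]], universe: int, flag_alpha: float = 0.01
) -> pd.DataFrame:
    """Pairwise shared counts and hypergeometric p across labelled cores.

    ``cores`` maps a label (e.g. "GHD_y1") to its gene set.  Returns a tidy
    table of pairs with shared counts, p-values and a significance flag at
    ``flag_alpha``.
    """
    labels = list(cores)
    if not labels:
        raise ValidationError("no cores given")
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i:]:
            if la == lb:
                shared, p = set(cores[la]), 0.0 if cores[la] else 1.0
                rows.append({"core_a": la, "core_b": lb, "n_a": len(set(cores[la])),
                             "n_b": len(set(cores[lb])), "shared": len(shared),
                             "p": np.nan, "flagged": False})
                continue
            shared, p = core_overlap_test(cores[la], cores[lb], universe)
            rows.append({"core_a": la, "core_b": lb, "n_a": len(set(cores[la])),
                         "n_b": len(set(cores[lb])), "shared": len(shared),
                         "p": p, "flagged": p < flag_alpha})
    return pd.DataFrame(rows)
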