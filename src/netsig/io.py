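"""Readers, writers, configuration and validation shared by every stage.

On-disk formats are plain text: tab-separated matrices (first column the
gene/marker id, header row of sample ids, ``#`` comments allowed), SIF or
two-column TSV edge lists for the interactome, JSON for truth/summary
objects, YAML for the pipeline configuration.  Numbers are written with 10
significant digits so write -> read round-trips are exact at that precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    GENOTYPE_CODES,
    MISSING_CODE,
    CohortPhenotype,
    ExpressionMatrix,
    GenotypeMatrix,
    MethylationMatrix,
    SyntheticTruth,
    ValidationError,
)

__all__ = [
    "PipelineConfig",
    "ParseError",
    "read_expression", "write_expression",
    "read_phenotype", "write_phenotype",
    "read_interactome", "write_interactome",
    "read_genotypes", "write_genotypes",
    "read_methylation", "write_methylation",
    "read_truth", "write_truth",
    "write_report",
]

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"
GENOTYPE_META_COLS = ["gene", "chromosome", "ld_block_id", "pseudoautosomal"]


class ParseError(ValidationError):
    """A file failed structural validation; the message names the location."""


@dataclass
class PipelineConfig:
    """All thresholds, sizes and seeds of the pipeline in one place."""

    # association thresholds
    assoc_p: float = 0.01          # rank-regression seed threshold
    signature_p: float = 0.05      # signature selection, either condition
    overlap_p: float = 0.01        # hypergeometric flag level
    methyl_p: float = 0.01         # methylation scan threshold
    methyl_r: float = 0.3          # |r| threshold for signature mapping
    # network landscape
    landscape_lambda: float = 0.5
    landscape_depth: int = 3
    membership_tau: float = 0.2
    metanode_size: int = 10
    # classification
    rf_trees: int = 1000
    boruta_perms: int = 100
    boruta_trees: int = 100
    smote_k: int = 5
    run_boruta: bool = False       # expensive; off in the default run
    # simulation scale (two conditions, study-sized cohorts)
    n_ghd: int = 70
    n_ts: int = 43
    n_genes_interactome: int = 9000
    n_genes_expressed: int = 8000
    module_size: int = 60
    p_in: float = 0.3
    p_out: float = 0.01
    clinical_r2_ghd: float = 0.61
    clinical_r2_ts: float = 0.46
    bio_r2: float = 0.25
    neg_methyl_fraction: float = 425.0 / 497.0
    n_markers: int = 1219
    n_ld_blocks: int = 768
    n_methyl_genes: int = 2000
    n_methyl_samples: int = 6
    null_effects: bool = False     # silence planted effects (null generator)
    # bookkeeping
    seed: int = 1
    endpoint: str = "hv"           # 'hv' per-year or 'cumulative'

    def __post_init__(self) -> None:
        for name in ("assoc_p", "signature_p", "overlap_p", "methyl_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} = {v} outside (0, 1)")
        for name in ("metanode_size", "rf_trees", "boruta_perms", "smote_k",
                     "landscape_depth", "n_ghd", "n_ts"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @property
    def clinical_r2(self) -> dict[str, float]:
        return {"GHD": self.clinical_r2_ghd, "TS": self.clinical_r2_ts}


def _check_header_unique(path: Path, what: str) -> None:
    # pandas mangles duplicate header names, so inspect the raw header line
    for line in path.read_text().splitlines():
        if line and not line.startswith("#"):
            cols = line.rstrip("\n").split("\t")[1:]
            dups = {c for c in cols if cols.count(c) > 1}
            if dups:
                raise ParseError(f"{what} {path}: duplicate sample id {sorted(dups)[0]!r}")
            return


def _read_tsv_matrix(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{what} file not found: {path}")
    _check_header_unique(path, what)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    df.columns.name = None
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ParseError(
                f"{what} {path}: non-numeric cell at row {row!r}, column {col!r}"
            )
        out[col] = converted
    return out


def _collapse_duplicates(df: pd.DataFrame, rule: str, what: str) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    dup = sorted(set(df.index[df.index.duplicated()]))
    log.info("%s: collapsing %d duplicate gene ids by %s", what, len(dup), rule)
    if rule == "max_variance":
        variances = df.var(axis=1)
        order = np.argsort(-variances.to_numpy(), kind="stable")
        keep = ~df.index[order].duplicated()
        kept_pos = order[keep]
        return df.iloc[np.sort(kept_pos)]
    if rule == "median":
        return df.groupby(level=0, sort=False).median()
    raise ValidationError(f"unknown duplicate-collapse rule {rule!r}")


def read_expression(
    path: str | Path,
    phenotype: CohortPhenotype | None = None,
    duplicate_rule: str = "max_variance",
) -> ExpressionMatrix:
    df = _read_tsv_matrix(path, "expression")
    df = _collapse_duplicates(df, duplicate_rule, "expression")
    if phenotype is not None:
        orphans = [s for s in df.columns if s not in phenotype.sample_ids]
        if orphans:
            raise ParseError(f"expression samples absent from phenotype: {orphans[:5]}")
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene_id")


def read_methylation(
    path: str | Path, duplicate_rule: str = "median"
) -> MethylationMatrix:
    df = _read_tsv_matrix(path, "methylation")
    df = _collapse_duplicates(df, duplicate_rule, "methylation")
    return MethylationMatrix(df)


def write_methylation(matrix: MethylationMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene_id")


PHENO_STR_COLS = ("condition", "sex", "batch")


def read_phenotype(path: str | Path) -> CohortPhenotype:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"phenotype file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"phenotype {path}: duplicate sample id {dup!r}")
    try:
        return CohortPhenotype(df)
    except ValidationError as err:
        raise ParseError(f"phenotype {path}: {err}") from err


def write_phenotype(phenotype: CohortPhenotype, path: str | Path) -> None:
    phenotype.table.to_csv(path, sep="\t", float_format=FLOAT_FMT,
                           index_label="sample_id")


def read_interactome(path: str | Path) -> nx.Graph:
    """Edge list as two-column TSV or SIF (``geneA pp geneB``) lines."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"interactome file not found: {path}")
    graph = nx.Graph()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 3 and parts[1] == "pp":  # SIF dialect
            a, b = parts[0], parts[2]
        elif len(parts) == 2:
            a, b = parts
        elif len(parts) == 1:
            graph.add_node(parts[0])
            continue
        else:
            raise ParseError(f"interactome {path}:{lineno}: unparseable line {line!r}")
        if not a or not b:
            raise ParseError(f"interactome {path}:{lineno}: empty gene id")
        if a != b:  # self-loops dropped: simple graph
            graph.add_edge(a, b)
        else:
            graph.add_node(a)
    return graph


def write_interactome(graph: nx.Graph, path: str | Path, dialect: str = "tsv") -> None:
    lines = []
    for a, b in sorted(map(sorted, graph.edges)):
        lines.append(f"{a} pp {b}" if dialect == "sif" else f"{a}\t{b}")
    for v in sorted(graph.nodes):
        if graph.degree(v) == 0:
            lines.append(str(v))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"genotype file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    missing_meta = [c for c in GENOTYPE_META_COLS if c not in df.columns]
    if missing_meta:
        raise ParseError(f"genotypes {path}: missing metadata columns {missing_meta}")
    meta = df[GENOTYPE_META_COLS].copy()
    meta["pseudoautosomal"] = meta["pseudoautosomal"].map(
        {"True": True, "False": False, "true": True, "false": False}
    )
    if meta["pseudoautosomal"].isna().any():
        row = meta.index[meta["pseudoautosomal"].isna()][0]
        raise ParseError(f"genotypes {path}: bad pseudoautosomal flag at {row!r}")
    calls = df.drop(columns=GENOTYPE_META_COLS).fillna(MISSING_CODE)
    allowed = set(GENOTYPE_CODES) | {MISSING_CODE}
    bad_mask = ~calls.isin(allowed)
    if bad_mask.any().any():
        stacked = bad_mask.stack()
        row, col = stacked[stacked].index[0]
        raise ParseError(
            f"genotypes {path}: unknown code {calls.loc[row, col]!r} "
            f"at marker {row!r}, sample {col!r}"
        )
    try:
        return GenotypeMatrix(calls, meta)
    except ValidationError as err:
        raise ParseError(f"genotypes {path}: {err}") from err


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    out = pd.concat([genotypes.meta, genotypes.calls], axis=1)
    out.to_csv(path, sep="\t", index_label="marker_id")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "planted_module_genes": sorted(truth.planted_module_genes),
        "per_condition_effect": {g: dict(e) for g, e in truth.per_condition_effect.items()},
        "clinical_r2": dict(truth.clinical_r2),
        "neg_methyl_fraction": truth.neg_methyl_fraction,
        "rng_seed": truth.rng_seed,
        "bio_r2": dict(truth.bio_r2),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        planted_module_genes=frozenset(payload["planted_module_genes"]),
        per_condition_effect=payload["per_condition_effect"],
        clinical_r2=payload["clinical_r2"],
        neg_methyl_fraction=payload["neg_methyl_fraction"],
        rng_seed=payload["rng_seed"],
        bio_r2=payload.get("bio_r2", {}),
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = list(obj) if not isinstance(obj, (set, frozenset)) else sorted(obj)
        return [_jsonable(v) for v in items]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def write_report(results: Mapping[str, Any], outdir: str | Path) -> dict[str, Path]:
    """Write stage tables (TSV) and a JSON summary with config echo and seeds.

    ``results`` maps names to DataFrames (written as ``<name>.tsv``) or to
    JSON-serializable objects collected into ``summary.json``.  Empty tables
    and empty signatures are written with an explicit marker rather than
    skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary: dict[str, Any] = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            target = outdir / f"{name}.tsv"
            if obj.empty:
                target.write_text("# empty table: no rows\n" +
                                  "\t".join(map(str, obj.columns)) + "\n")
            else:
                obj.to_csv(target, sep="\t", index=False, float_format=FLOAT_FMT)
            written[name] = target
        else:
            summary[name] = _jsonable(obj)
    target = outdir / "summary.json"
    target.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written["summary"] = target
    return written
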