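"""Readers and writers for the plain-text formats the pipeline touches.

Expression, purity, survival and result tables travel as TSV; gene sets as
GMT (tab-separated: name, description, member genes); models and manifests
as JSON. All writers use a fixed float format so that reruns with the same
seed are byte-identical.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, check_purity, check_survival

FLOAT_FORMAT = "%.10g"


# -- expression -----------------------------------------------------------

def read_expression(path, partition_path=None, lnc_prefix="LNC_") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header sample ids).

    The mRNA/lncRNA partition comes from *partition_path* (two-column TSV:
    gene, partition) when given, otherwise from the gene-id prefix rule.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = None
    if partition_path is not None:
        part = pd.read_csv(partition_path, sep="\t", index_col=0).iloc[:, 0]
        part.index = part.index.astype(str)
        part.index.name = None
        return ExpressionMatrix(values, part)
    return ExpressionMatrix.from_prefix(values, lnc_prefix=lnc_prefix)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


def write_partition(expr: ExpressionMatrix, path) -> None:
    expr.partition.rename("partition").to_csv(path, sep="\t", index_label="gene")


# -- purity / survival ----------------------------------------------------

def read_purity(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return check_purity(df.iloc[:, 0])


def write_purity(purity: pd.Series, path) -> None:
    purity.rename("purity").to_csv(path, sep="\t", index_label="sample", float_format=FLOAT_FORMAT)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return check_survival(df)


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index_label="sample", float_format=FLOAT_FORMAT)


# -- gene sets (GMT) ------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets, source=str(path))


def write_gmt(sets: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# -- generic tables / JSON ------------------------------------------------

def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None,
              index_label=index_label, float_format=FLOAT_FORMAT)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
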