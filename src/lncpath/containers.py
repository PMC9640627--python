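"""Core data containers shared across all pipeline stages.

The pipeline operates on four aligned objects: a gene-level expression matrix
partitioned into mRNAs and lncRNAs, a per-sample tumor-purity vector, a
survival table (time, event), and a collection of named gene sets. Containers
validate their invariants at construction so downstream stages can assume
clean inputs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MRNA = "mRNA"
LNCRNA = "lncRNA"

#: default identifier prefixes used to infer the mRNA/lncRNA partition
LNC_PREFIX = "LNC_"
MRNA_PREFIX = "MRNA_"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with an mRNA/lncRNA partition label.

    Parameters
    ----------
    values
        DataFrame of continuous (log-scale) expression, index = gene ids,
        columns = sample ids.
    partition
        Series mapping every gene id to ``"mRNA"`` or ``"lncRNA"``.
    """

    values: pd.DataFrame
    partition: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 samples")
        if v.isna().any().any():
            raise ValueError("expression contains missing values")
        part = self.partition.reindex(v.index)
        if part.isna().any():
            missing = part.index[part.isna()][:5].tolist()
            raise ValueError(f"partition missing for genes: {missing}")
        bad = set(part.unique()) - {MRNA, LNCRNA}
        if bad:
            raise ValueError(f"unknown partition labels: {sorted(bad)}")
        self.partition = part
        self.values = v.astype(float)

    # -- convenience views ------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def mrna(self) -> pd.DataFrame:
        """mRNA rows of the matrix."""
        return self.values.loc[self.partition == MRNA]

    @property
    def lncrna(self) -> pd.DataFrame:
        """lncRNA rows of the matrix."""
        return self.values.loc[self.partition == LNCRNA]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.partition)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        return ExpressionMatrix(self.values.loc[gene_ids], self.partition.loc[gene_ids])

    @classmethod
    def from_prefix(cls, values: pd.DataFrame, lnc_prefix: str = LNC_PREFIX) -> "ExpressionMatrix":
        """Infer the partition from gene-id prefixes (lncRNAs start with *lnc_prefix*)."""
        part = pd.Series(
            np.where(values.index.str.startswith(lnc_prefix), LNCRNA, MRNA),
            index=values.index,
        )
        return cls(values, part)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. MSigDB hallmark collection read from GMT)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("duplicate set names")
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def check_purity(purity: pd.Series, sample_ids=None) -> pd.Series:
    """Validate a tumor-purity vector: values in [0, 1], covering *sample_ids*."""
    purity = purity.astype(float)
    if purity.index.has_duplicates:
        raise ValueError("duplicate sample identifiers in purity")
    if ((purity < 0) | (purity > 1)).any():
        raise ValueError("purity values must lie in [0, 1]")
    if sample_ids is not None:
        missing = set(sample_ids) - set(purity.index)
        if missing:
            raise ValueError(f"purity missing for samples: {sorted(missing)[:5]}")
        purity = purity.reindex(list(sample_ids))
    return purity


def check_survival(surv: pd.DataFrame, sample_ids=None) -> pd.DataFrame:
    """Validate a survival table indexed by sample with ``time`` and ``event``.

    Times must be strictly positive; event is coded 0 = censored, 1 = death.
    """
    if not {"time", "event"}.issubset(surv.columns):
        raise ValueError("survival table needs 'time' and 'event' columns")
    if surv.index.has_duplicates:
        raise ValueError("duplicate sample identifiers in survival table")
    surv = surv[["time", "event"]].astype({"time": float, "event": int})
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be strictly positive")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
    if sample_ids is not None:
        missing = set(sample_ids) - set(surv.index)
        if missing:
            raise ValueError(f"survival missing for samples: {sorted(missing)[:5]}")
        surv = surv.reindex(list(sample_ids))
    return surv
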