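"""Core containers: probe-level expression matrix and per-sample metadata.

The expression matrix is probes x samples of log2 intensities (dimensionless;
values may be negative after normalization).  Every probe carries a gene
symbol so panels defined at gene level can be resolved to one or more probes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("CNTRL", "SIRS", "ABDM", "PLMN")
SEPSIS_GROUPS = ("ABDM", "PLMN")
DISEASE_GROUPS = ("SIRS", "ABDM", "PLMN")
TIMEPOINTS = ("D1", "D2", "D5", "DC")

_GENE_COL = "gene"
_PROBE_COL = "probe_id"


@dataclass
class ExpressionMatrix:
    """Probes x samples of log2 intensity with a probe -> gene mapping.

    ``values`` is a DataFrame indexed by probe id with sample ids as columns;
    ``genes`` is a Series aligned to the probe index.  Missingness is only
    allowed as whole-sample absence (a sample simply has no column), never as
    NaN cells.
    """

    values: pd.DataFrame
    genes: pd.Series = None

    def __post_init__(self) -> None:
        if self.genes is None:
            self.genes = pd.Series(self.values.index, index=self.values.index)
        self.genes = self.genes.reindex(self.values.index)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.genes.isna().any():
            raise ValueError("probes without a gene mapping")

    # -- basic views ------------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.genes.copy())

    def probes_for_gene(self, gene: str) -> list[str]:
        return list(self.genes.index[self.genes == gene])

    def subset(self, probes=None, samples=None) -> "ExpressionMatrix":
        vals = self.values
        if probes is not None:
            vals = vals.loc[list(probes)]
        if samples is not None:
            vals = vals[list(samples)]
        return ExpressionMatrix(vals, self.genes.reindex(vals.index))

    # -- TSV dialect ------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write probes-as-rows TSV: probe_id, gene, then one column per sample."""
        out = self.values.copy()
        out.insert(0, _GENE_COL, self.genes)
        out.index.name = _PROBE_COL
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if _GENE_COL in df.columns:
            genes = df[_GENE_COL].astype(str)
            vals = df.drop(columns=[_GENE_COL])
        else:
            genes = pd.Series(df.index, index=df.index)
            vals = df
        return cls(vals.astype(float), genes)


@dataclass
class SampleAnnotation:
    """Per-sample group / timepoint / survival labels.

    ``table`` is indexed by sample id with columns ``subject_id``, ``group``,
    ``timepoint`` and ``survival`` ("S" survived / "DNS" did not survive).
    """

    table: pd.DataFrame

    REQUIRED = ("subject_id", "group", "timepoint", "survival")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in annotation")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples(self, groups=None, timepoint=None, survival=None) -> list[str]:
        """Sample ids matching the given group(s) / timepoint / survival."""
        mask = np.ones(len(self.table), dtype=bool)
        if groups is not None:
            if isinstance(groups, str):
                groups = (groups,)
            mask &= self.table["group"].isin(groups).to_numpy()
        if timepoint is not None:
            mask &= (self.table["timepoint"] == timepoint).to_numpy()
        if survival is not None:
            mask &= (self.table["survival"] == survival).to_numpy()
        return list(self.table.index[mask])

    def labels(self, positive_groups, sample_ids=None) -> np.ndarray:
        """0/1 vector over sample_ids, 1 for samples in positive_groups."""
        if isinstance(positive_groups, str):
            positive_groups = (positive_groups,)
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        sub = self.table.loc[ids]
        return sub["group"].isin(positive_groups).to_numpy().astype(int)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SampleAnnotation":
        return cls(pd.read_csv(path, sep="\t", index_col=0))
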