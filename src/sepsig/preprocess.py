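"""Microarray-style normalization and probe filtering on log2 matrices.

Pipeline order: per-sample percentile shift (75th percentile to zero), then
per-probe baseline median transform, then the expression-range outlier filter
and the sex-linked probe blacklist.  Downstream modules assume the per-probe
median is ~0, which is the scale on which negative panel cut-offs live.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "percentile_shift", "baseline_median_transform", "filter_by_range",
    "drop_probes", "run_preprocess", "ProbeFilterReport", "DEFAULT_BLACKLIST",
    "read_series_matrix",
]

# Predominantly X/Y-linked genes removed ahead of differential analysis.
DEFAULT_BLACKLIST = ("DDX3Y", "PSPHP1", "XIST", "RPS4Y1", "RPS4Y2", "BTNL8")


@dataclass
class ProbeFilterReport:
    n_before: int
    n_after: int
    removed_out_of_range: list = field(default_factory=list)
    removed_blacklist: list = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.removed_out_of_range) & set(self.removed_blacklist)
        if overlap:
            raise ValueError("removal lists must be disjoint")
        n_removed = len(self.removed_out_of_range) + len(self.removed_blacklist)
        if self.n_after != self.n_before - n_removed:
            raise ValueError("inconsistent filter report counts")


def percentile_shift(matrix: ExpressionMatrix, q: float = 0.75) -> ExpressionMatrix:
    """Subtract each sample's q-quantile so its q-quantile becomes exactly 0.

    The quantile is the linear-interpolation ("type 7") definition.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    vals = matrix.values
    if vals.shape[0] == 0:
        raise ValueError("empty matrix")
    shifts = np.quantile(vals.to_numpy(), q, axis=0, method="linear")
    return ExpressionMatrix(vals - shifts, matrix.genes.copy())


def baseline_median_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each probe's median across samples (per-probe zero-centring)."""
    vals = matrix.values
    if vals.shape[1] == 0:
        raise ValueError("matrix has no samples")
    med = np.median(vals.to_numpy(), axis=1)
    return ExpressionMatrix(vals.sub(med, axis=0), matrix.genes.copy())


def filter_by_range(matrix: ExpressionMatrix, lo: float = -7.0,
                    hi: float = 7.0) -> tuple[ExpressionMatrix, ProbeFilterReport]:
    """Remove probes with any value strictly outside [lo, hi]."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    vals = matrix.values.to_numpy()
    out = (vals < lo) | (vals > hi)
    bad = matrix.values.index[out.any(axis=1)]
    kept = matrix.subset(probes=matrix.values.index.difference(bad, sort=False))
    report = ProbeFilterReport(matrix.shape[0], kept.shape[0],
                               removed_out_of_range=list(bad))
    return kept, report


def drop_probes(matrix: ExpressionMatrix,
                blacklist=DEFAULT_BLACKLIST) -> tuple[ExpressionMatrix, ProbeFilterReport]:
    """Remove every probe mapped to a blacklisted gene (absent genes are no-ops)."""
    bad = matrix.genes.index[matrix.genes.isin(set(blacklist))]
    kept = matrix.subset(probes=matrix.values.index.difference(bad, sort=False))
    report = ProbeFilterReport(matrix.shape[0], kept.shape[0],
                               removed_blacklist=list(bad))
    return kept, report


def run_preprocess(matrix: ExpressionMatrix, q: float = 0.75, lo: float = -7.0,
                   hi: float = 7.0, blacklist=DEFAULT_BLACKLIST):
    """Full pipeline: percentile shift -> median transform -> range filter -> blacklist."""
    m = baseline_median_transform(percentile_shift(matrix, q=q))
    m, range_report = filter_by_range(m, lo=lo, hi=hi)
    m, blk_report = drop_probes(m, blacklist=blacklist)
    report = ProbeFilterReport(
        range_report.n_before, blk_report.n_after,
        removed_out_of_range=range_report.removed_out_of_range,
        removed_blacklist=blk_report.removed_blacklist,
    )
    return m, report


def read_series_matrix(path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Minimal GEO series-matrix reader for external panel evaluation.

    Parses the sample metadata lines (``!Sample_*``) and the expression block
    between the table-begin/end markers.  Returns the matrix (probe ids as
    given, genes defaulting to probe ids) and a sample metadata DataFrame.
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key, *vals = line.split("\t")
                meta.setdefault(key[len("!Sample_"):], []).extend(
                    v.strip('"') for v in vals)
    if not table_lines:
        raise ValueError("no expression table found in series-matrix file")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    mat = ExpressionMatrix(df.astype(float))
    meta_df = pd.DataFrame(meta)
    if "geo_accession" in meta_df.columns:
        meta_df = meta_df.set_index("geo_accession")
    return mat, meta_df
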