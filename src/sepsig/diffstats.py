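"""Differential-expression and clinical-parameter statistics.

Signed fold change on the log2 scale, Welch/pooled t-tests, one-way ANOVA,
Benjamini-Hochberg FDR, Mann-Whitney U (exact for small untied samples) and
PCA sample scores with a deterministic sign convention.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, SampleAnnotation

__all__ = [
    "fold_change", "log2_fold_change", "t_test", "one_way_anova", "bh_fdr",
    "mann_whitney", "pca_scores", "probe_stats_table", "anova_qvalues",
]

# Combined-sample-size switch point between exact and normal-approximation
# Mann-Whitney branches.
EXACT_MW_MAX_N = 12


def log2_fold_change(a, b) -> float:
    """Difference of group mean log2 expression, mean(a) - mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    return float(a.mean() - b.mean())


def fold_change(a, b) -> float:
    """Signed linear fold change: +2^d if d >= 0 else -2^(-d), d = mean(a)-mean(b).

    Always |FC| >= 1; the sign carries the direction of regulation.
    """
    d = log2_fold_change(a, b)
    return float(2.0 ** d) if d >= 0 else float(-(2.0 ** (-d)))


def t_test(a, b, welch: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test; Welch (Satterthwaite df) by default.

    Zero variance in both groups with equal means returns (0, 1) by
    convention (no evidence of a difference from constant data).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def one_way_anova(groups) -> tuple[float, float]:
    """Classical between/within mean-square F ratio with p from the F distribution.

    Degenerate conventions: all values identical -> (0, 1); zero within-group
    variance with differing means -> (inf, 0).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    n = sum(g.size for g in arrays)
    k = len(arrays)
    grand = sum(g.sum() for g in arrays) / n
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float(np.inf), 0.0
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U of a vs b with two-sided p.

    Exact p by enumeration when the combined n <= 12 and there are no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= EXACT_MW_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def pca_scores(matrix: ExpressionMatrix, k: int) -> pd.DataFrame:
    """Sample scores of the first k principal components of probe-centred data.

    Components are the eigenvectors of the sample covariance after centring
    each probe; signs are fixed so each component's largest-magnitude probe
    loading is positive.  Raises if k exceeds the data rank.
    """
    X = matrix.values.to_numpy().T  # samples x probes
    if k > min(X.shape):
        raise ValueError("k exceeds matrix dimensions")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    rank = int((S > tol).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds data rank {rank}")
    scores = U[:, :k] * S[:k]
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, index=matrix.sample_ids,
                        columns=[f"PC{j + 1}" for j in range(k)])


# ---------------------------------------------------------------------------
# Bulk per-probe tables
# ---------------------------------------------------------------------------

def probe_stats_table(matrix: ExpressionMatrix, annotation: SampleAnnotation,
                      group_a, group_b, timepoint=None,
                      welch: bool = True) -> pd.DataFrame:
    """Volcano table: per-probe signed FC, log2 FC, t, p and BH-FDR q.

    group_a / group_b may be single groups or tuples of groups; the FC sign
    convention is group_a over group_b.
    """
    sa = annotation.samples(groups=group_a, timepoint=timepoint)
    sb = annotation.samples(groups=group_b, timepoint=timepoint)
    if not sa or not sb:
        raise ValueError("empty group selection")
    A = matrix.values[sa].to_numpy()
    B = matrix.values[sb].to_numpy()
    d = A.mean(axis=1) - B.mean(axis=1)
    fc = np.where(d >= 0, 2.0 ** d, -(2.0 ** (-d)))
    t, p = stats.ttest_ind(A, B, axis=1, equal_var=not welch)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_fdr(p)
    return pd.DataFrame(
        {"gene": matrix.genes.to_numpy(), "fc": fc, "log2fc": d,
         "t": t, "p": p, "q": q},
        index=matrix.values.index,
    )


def anova_qvalues(matrix: ExpressionMatrix, annotation: SampleAnnotation,
                  groups, timepoint=None) -> pd.DataFrame:
    """Per-probe one-way ANOVA across groups with BH-FDR q-values."""
    arrays = []
    for g in groups:
        ids = annotation.samples(groups=g, timepoint=timepoint)
        if len(ids) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
        arrays.append(matrix.values[ids].to_numpy())
    f, p = stats.f_oneway(*arrays, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_fdr(p)
    return pd.DataFrame({"gene": matrix.genes.to_numpy(), "f": f, "p": p, "q": q},
                        index=matrix.values.index)
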