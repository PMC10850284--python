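"""Signed additive panel scoring and ROC / cut-off / diagnostic metrics.

A panel is an ordered list of (gene, sign) terms; a sample's composite score
is the signed sum of its normalized expression values, genes upregulated in
the positive class entering with +1 and downregulated genes with -1.  On the
zero-centred post-normalization scale these scores are typically negative,
hence the negative published cut-offs.

ROC analysis follows the pair-counting definition of the AUC (probability a
random positive outscores a random negative, ties half-counted) with the
Hanley-McNeil standard error and z-interval CIs.  Cut-offs are "predict
positive iff score > cutoff" thresholds at midpoints between distinct
scores; diagnostic metrics carry Clopper-Pearson exact 95% CIs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, SampleAnnotation

__all__ = [
    "PanelTerm", "PanelDefinition", "RocCurve", "DiagnosticMetrics",
    "PanelReport", "composite_score", "roc_auc", "auc_ci",
    "likelihood_ratios", "best_cutoff", "diagnostics_at",
    "threshold_for_target", "evaluate_panel", "correlate_markers",
    "load_presets", "hanley_mcneil_se",
]


# ---------------------------------------------------------------------------
# Panel definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelTerm:
    gene: str
    sign: int  # +1 or -1
    probe: str | None = None  # used by the named_probe collapse policy

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")


@dataclass
class PanelDefinition:
    """Ordered signed gene list plus the multi-probe collapse policy.

    probe_policy: "best_auc" picks, per gene, the probe whose single-probe
    AUC against the comparison labels is highest; "mean" averages probes;
    "named_probe" uses each term's explicit probe id.
    """

    name: str
    terms: list
    probe_policy: str = "best_auc"

    def __post_init__(self):
        genes = [t.gene for t in self.terms]
        if len(set(genes)) != len(genes):
            raise ValueError("panel genes must be distinct")
        if not self.terms:
            raise ValueError("panel needs at least one term")
        if self.probe_policy not in ("best_auc", "mean", "named_probe"):
            raise ValueError(f"unknown probe policy {self.probe_policy!r}")

    @property
    def genes(self) -> list:
        return [t.gene for t in self.terms]

    @classmethod
    def parse(cls, spec: str, name: str | None = None,
              probe_policy: str = "best_auc") -> "PanelDefinition":
        """Parse "GENE1+GENE2-GENE3" (leading sign optional, defaults +)."""
        s = spec.strip()
        if not s:
            raise ValueError("empty panel specification")
        if s[0] not in "+-":
            s = "+" + s
        terms = []
        token = ""
        sign = +1
        for ch in s:
            if ch in "+-":
                if token:
                    terms.append(PanelTerm(token, sign))
                sign = +1 if ch == "+" else -1
                token = ""
            else:
                token += ch
        if token:
            terms.append(PanelTerm(token, sign))
        return cls(name or spec.strip(), terms, probe_policy)

    def __str__(self) -> str:
        out = ""
        for i, t in enumerate(self.terms):
            if t.sign > 0 and i > 0:
                out += "+"
            elif t.sign < 0:
                out += "-"
            out += t.gene
        return out


def load_presets() -> dict:
    """Named preset panels from the shipped catalogue (panel, gene, sign, source)."""
    path = resources.files("sepsig").joinpath("presets.tsv")
    with resources.as_file(path) as p:
        cat = pd.read_csv(p, sep="\t")
    panels = {}
    for name, grp in cat.groupby("panel", sort=False):
        terms = [PanelTerm(r.gene, int(r.sign)) for r in grp.itertuples()]
        panels[name] = PanelDefinition(name, terms)
    return panels


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _collapse_gene(matrix: ExpressionMatrix, term: PanelTerm, policy: str,
                   samples, labels) -> np.ndarray:
    probes = matrix.probes_for_gene(term.gene)
    if not probes:
        raise KeyError(f"panel gene {term.gene!r} has no probe in the matrix")
    vals = matrix.values.loc[probes, samples]
    if len(probes) == 1:
        return vals.to_numpy()[0]
    if policy == "mean":
        return vals.mean(axis=0).to_numpy()
    if policy == "named_probe":
        if term.probe is None or term.probe not in probes:
            raise ValueError(f"{term.gene}: named_probe policy needs a valid probe id")
        return matrix.values.loc[term.probe, samples].to_numpy()
    # best_auc: probe maximizing the oriented single-probe AUC
    if labels is None:
        raise ValueError("best_auc probe collapse requires comparison labels")
    best, best_auc_val = None, -1.0
    for pr in probes:
        v = matrix.values.loc[pr, samples].to_numpy() * term.sign
        a = _auc_value(v, labels)
        if a > best_auc_val:
            best, best_auc_val = pr, a
    return matrix.values.loc[best, samples].to_numpy()


def composite_score(panel: PanelDefinition, matrix: ExpressionMatrix,
                    samples=None, labels=None) -> pd.Series:
    """Per-sample signed additive score: sum of sign * collapsed probe value."""
    if samples is None:
        samples = matrix.sample_ids
    samples = list(samples)
    score = np.zeros(len(samples))
    for term in panel.terms:
        score += term.sign * _collapse_gene(matrix, term, panel.probe_policy,
                                            samples, labels)
    return pd.Series(score, index=samples, name=panel.name)


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    thresholds: np.ndarray  # midpoints between distinct scores, with -inf/+inf ends
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    se: float
    n_pos: int
    n_neg: int

    def ci(self, level: float = 0.90) -> tuple[float, float]:
        return auc_ci(self.auc, self.se, level)


def _auc_value(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pair-counting AUC via midranks: (#{pos>neg} + 0.5 #ties) / (n_pos n_neg)."""
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil SE with Q1 = A/(2-A) and Q2 = 2A^2/(1+A)."""
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1.0 - a) + (n_pos - 1) * (q1 - a * a)
           + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def _midpoint_thresholds(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def roc_auc(scores, labels) -> RocCurve:
    """Full ROC curve with pair-counting AUC and Hanley-McNeil SE."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc = _auc_value(scores, labels)  # raises on single class
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    thr = _midpoint_thresholds(scores)
    sens = np.array([(scores[pos] > t).mean() for t in thr])
    spec = np.array([(scores[~pos] <= t).mean() for t in thr])
    return RocCurve(thr, sens, spec, auc, hanley_mcneil_se(auc, n_pos, n_neg),
                    n_pos, n_neg)


def auc_ci(auc: float, se: float, level: float = 0.90) -> tuple[float, float]:
    """z-interval auc +/- z(level) * se, clipped to [0, 1]."""
    if not 0.0 <= auc <= 1.0 or se < 0:
        raise ValueError("auc must be in [0,1] and se >= 0")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def likelihood_ratios(sensitivity_pct: float, specificity_pct: float) -> tuple[float, float]:
    """LR+ = sens/(100-spec), LR- = (100-sens)/spec on the percent scale.

    Infinity is a defined return at the respective zero denominators.
    """
    if not (0 <= sensitivity_pct <= 100 and 0 <= specificity_pct <= 100):
        raise ValueError("sensitivity/specificity must be percentages in [0, 100]")
    lr_pos = np.inf if specificity_pct == 100 else sensitivity_pct / (100.0 - specificity_pct)
    lr_neg = np.inf if specificity_pct == 0 else (100.0 - sensitivity_pct) / specificity_pct
    return float(lr_pos), float(lr_neg)


# ---------------------------------------------------------------------------
# Cut-offs and diagnostics
# ---------------------------------------------------------------------------

def _confusion(scores, labels, cutoff):
    pred = scores > cutoff
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return tp, fp, tn, fn


def best_cutoff(scores, labels) -> float:
    """Accuracy-maximal midpoint threshold; ties by max Youden J, then smallest."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes required")
    best = None
    for t in _midpoint_thresholds(scores):
        tp, fp, tn, fn = _confusion(scores, labels, t)
        acc = (tp + tn) / len(scores)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        key = (acc, sens + spec - 1.0, -t)
        if best is None or key > best[0]:
            best = (key, t)
    return float(best[1])


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class DiagnosticMetrics:
    """Confusion counts and the eight diagnostic metrics at one cut-off.

    Fractions (not percentages); CIs are Clopper-Pearson exact 95% two-sided.
    A 0/0 predictive value is reported as NaN and named in ``undefined``.
    """

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    sensitivity_ci: tuple
    specificity_ci: tuple
    ppv_ci: tuple
    npv_ci: tuple
    undefined: tuple = ()

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)


def diagnostics_at(scores, labels, cutoff: float) -> DiagnosticMetrics:
    """All diagnostic metrics with 'positive iff score > cutoff'."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes required")
    tp, fp, tn, fn = _confusion(scores, labels, cutoff)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    undefined = []
    if tp + fp == 0:
        ppv, ppv_ci = float("nan"), (float("nan"), float("nan"))
        undefined.append("ppv")
    else:
        ppv, ppv_ci = tp / (tp + fp), _clopper_pearson(tp, tp + fp)
    if tn + fn == 0:
        npv, npv_ci = float("nan"), (float("nan"), float("nan"))
        undefined.append("npv")
    else:
        npv, npv_ci = tn / (tn + fn), _clopper_pearson(tn, tn + fn)
    lr_pos = np.inf if spec == 1.0 else sens / (1.0 - spec)
    lr_neg = np.inf if spec == 0.0 else (1.0 - sens) / spec
    return DiagnosticMetrics(
        cutoff=float(cutoff), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        lr_pos=float(lr_pos), lr_neg=float(lr_neg),
        sensitivity_ci=_clopper_pearson(tp, tp + fn),
        specificity_ci=_clopper_pearson(tn, tn + fp),
        ppv_ci=ppv_ci, npv_ci=npv_ci, undefined=tuple(undefined),
    )


def threshold_for_target(scores, labels, metric: str, target: float) -> float | None:
    """Smallest-yield-loss cut-off achieving a PPV or NPV target, or None.

    Scans all midpoint thresholds; among those with metric >= target, returns
    the one maximizing the complementary yield (sensitivity for a PPV target,
    specificity for an NPV target); ties are resolved by the other yield,
    then by the smaller threshold.
    """
    if metric not in ("ppv", "npv"):
        raise ValueError("metric must be 'ppv' or 'npv'")
    if not 0.0 < target < 1.0:
        raise ValueError("target must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    best = None
    for t in _midpoint_thresholds(scores):
        d = diagnostics_at(scores, labels, t)
        value = d.ppv if metric == "ppv" else d.npv
        if math.isnan(value) or value < target:
            continue
        if metric == "ppv":
            key = (d.sensitivity, d.specificity, -t)
        else:
            key = (d.specificity, d.sensitivity, -t)
        if best is None or key > best[0]:
            best = (key, t)
    return None if best is None else float(best[1])


# ---------------------------------------------------------------------------
# Panel evaluation and marker correlation
# ---------------------------------------------------------------------------

@dataclass
class PanelReport:
    """Full per-comparison evaluation of one panel.

    If any panel gene is missing from the matrix the evaluation aborts:
    missing_genes is populated and everything else is None (no imputation).
    indeterminate_zone is the open score interval between the NPV-target and
    PPV-target cut-offs, where the test result is treated as inconclusive.
    """

    panel: PanelDefinition
    comparison: tuple
    missing_genes: list = field(default_factory=list)
    scores: pd.Series | None = None
    labels: np.ndarray | None = None
    roc: RocCurve | None = None
    best: DiagnosticMetrics | None = None
    ppv_cutoff: float | None = None
    ppv_diag: DiagnosticMetrics | None = None
    npv_cutoff: float | None = None
    npv_diag: DiagnosticMetrics | None = None

    @property
    def evaluated(self) -> bool:
        return self.roc is not None

    @property
    def indeterminate_zone(self) -> tuple | None:
        if self.ppv_cutoff is None or self.npv_cutoff is None:
            return None
        lo, hi = sorted((self.npv_cutoff, self.ppv_cutoff))
        return (lo, hi)


def evaluate_panel(panel: PanelDefinition, matrix: ExpressionMatrix,
                   annotation: SampleAnnotation, comparison,
                   timepoint=None, ppv_target: float = 0.95,
                   npv_target: float = 0.98) -> PanelReport:
    """Score a panel on (positive groups, negative groups) and report ROC + cut-offs.

    Genes absent from the matrix are reported and the panel is not scored
    (no silent imputation).
    """
    pos_groups, neg_groups = comparison
    missing = [g for g in panel.genes if not matrix.probes_for_gene(g)]
    report = PanelReport(panel=panel, comparison=comparison, missing_genes=missing)
    if missing:
        return report
    pos = annotation.samples(groups=pos_groups, timepoint=timepoint)
    neg = annotation.samples(groups=neg_groups, timepoint=timepoint)
    if not pos or not neg:
        raise ValueError("comparison groups are empty at this timepoint")
    samples = pos + neg
    labels = np.array([1] * len(pos) + [0] * len(neg))
    scores = composite_score(panel, matrix, samples=samples, labels=labels)
    s = scores.to_numpy()
    report.scores = scores
    report.labels = labels
    report.roc = roc_auc(s, labels)
    report.best = diagnostics_at(s, labels, best_cutoff(s, labels))
    report.ppv_cutoff = threshold_for_target(s, labels, "ppv", ppv_target)
    if report.ppv_cutoff is not None:
        report.ppv_diag = diagnostics_at(s, labels, report.ppv_cutoff)
    report.npv_cutoff = threshold_for_target(s, labels, "npv", npv_target)
    if report.npv_cutoff is not None:
        report.npv_diag = diagnostics_at(s, labels, report.npv_cutoff)
    return report


def correlate_markers(matrix: ExpressionMatrix, genes, extra: dict | None = None,
                      samples=None) -> pd.DataFrame:
    """Pairwise Spearman correlations (mid-rank ties) of marker expression.

    Multi-probe genes are collapsed by their per-sample mean; ``extra`` adds
    named clinical vectors (aligned to the selected samples).  Constant
    vectors yield NaN correlations.
    """
    if samples is None:
        samples = matrix.sample_ids
    samples = list(samples)
    cols = {}
    for g in genes:
        probes = matrix.probes_for_gene(g)
        if not probes:
            raise KeyError(f"gene {g!r} not in matrix")
        cols[g] = matrix.values.loc[probes, samples].mean(axis=0).to_numpy()
    for name, vec in (extra or {}).items():
        vec = np.asarray(vec, dtype=float)
        if vec.size != len(samples):
            raise ValueError(f"extra vector {name!r} misaligned with samples")
        cols[name] = vec
    if len(cols) < 2:
        raise ValueError("need at least two vectors to correlate")
    return pd.DataFrame(cols, index=samples).corr(method="spearman")
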