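"""Seeded synthetic ICU cohorts with the statistical structure the analysis assumes.

Emulates a four-group microarray study (healthy controls, SIRS after
out-of-hospital cardiac arrest, abdominal sepsis, pulmonary sepsis) sampled at
up to four timepoints with attrition, planted log2-scale expression effects,
and a clinical covariate table (CRP, cell counts, severity scores) drawn
log-normally from published per-group median/IQR summaries.

The generator is the test harness for every downstream stage: expression
values are per-probe baseline + group/timepoint shift + independent Gaussian
noise on the log2 scale, so fold-change algebra is exact and recovery of
planted effects is a well-defined event.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .matrix import (DISEASE_GROUPS, GROUPS, SEPSIS_GROUPS, TIMEPOINTS,
                     ExpressionMatrix, SampleAnnotation)

__all__ = [
    "CohortDesign", "PlantedEffect", "generate_cohort", "simulate_clinical",
    "realized_fold_change", "ioi_effects", "sos_effects", "TABLE1_TARGETS",
]

# Survival fractions per group, from the published cohort summary.
DEFAULT_SURVIVAL = {"CNTRL": 1.0, "SIRS": 0.611, "ABDM": 0.745, "PLMN": 0.784}
DEFAULT_GROUP_SIZES = {"CNTRL": 30, "SIRS": 42, "ABDM": 59, "PLMN": 84}
# Temporal decay of planted log2 shifts toward discharge (D1, D2, D5, DC).
DEFAULT_TEMPORAL = (1.0, 0.9, 0.6, 0.3)


@dataclass
class CohortDesign:
    """Cohort layout and noise model parameters.

    probe_noise_sd and baseline_sd are in log2 units.  dropout_prob is the
    per-later-timepoint probability that a patient's sample is missing;
    non-survivors are additionally penalised at D5/DC by
    nonsurvivor_dropout_factor (samples not collected due to death).
    Controls are sampled at the first timepoint only.
    """

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    timepoints: tuple = TIMEPOINTS
    n_probes: int = 2000
    probe_noise_sd: float = 0.5
    baseline_sd: float = 1.5
    dropout_prob: float = 0.15
    nonsurvivor_dropout_factor: float = 2.0
    survival_prob: dict = field(default_factory=lambda: dict(DEFAULT_SURVIVAL))
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n <= 0:
                raise ValueError(f"group size for {g} must be > 0")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoints must be unique")
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        for g, p in self.survival_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"survival probability for {g} not in [0, 1]")
        if self.probe_noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class PlantedEffect:
    """A gene with a group-specific signed linear fold change at Day1.

    fold_change follows the signed convention (+2^d for up, -2^(-d) for
    down, |FC| >= 1).  The log2 shift decays over timepoints by
    temporal_profile, and non-survivors receive an extra log2 shift of
    survival_modifier.  n_probes > 1 emits duplicate probes sharing the
    effect with independent noise (duplicate array probes per gene).
    """

    gene: str
    affected_groups: tuple
    fold_change: float
    temporal_profile: tuple = DEFAULT_TEMPORAL
    survival_modifier: float = 0.0
    n_probes: int = 1

    def validate(self, timepoints) -> None:
        if abs(self.fold_change) < 1.0:
            raise ValueError(f"{self.gene}: |fold_change| must be >= 1")
        if any(m < 0 for m in self.temporal_profile):
            raise ValueError(f"{self.gene}: temporal multipliers must be >= 0")
        if len(self.temporal_profile) < len(timepoints):
            raise ValueError(f"{self.gene}: temporal profile shorter than timepoints")
        unknown = set(self.affected_groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"{self.gene}: unknown groups {sorted(unknown)}")
        if self.n_probes < 1:
            raise ValueError(f"{self.gene}: n_probes must be >= 1")

    @property
    def log2_shift(self) -> float:
        s = math.log2(abs(self.fold_change))
        return s if self.fold_change >= 0 else -s


def generate_cohort(design: CohortDesign, effects=()) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Draw a reproducible synthetic cohort.

    Returns the log2 expression matrix (planted probes first) and the sample
    annotation.  Attrition is monotone: a patient present at a later
    timepoint is present at all earlier ones.
    """
    design.validate()
    effects = list(effects)
    for e in effects:
        e.validate(design.timepoints)
    n_planted_probes = sum(e.n_probes for e in effects)
    if n_planted_probes > design.n_probes:
        raise ValueError("n_probes smaller than the number of planted probes")
    if len({e.gene for e in effects}) != len(effects):
        raise ValueError("duplicate planted genes")

    rng = np.random.default_rng(design.seed)

    # --- annotation -----------------------------------------------------
    rows = []
    for group in GROUPS:
        n = design.group_sizes.get(group, 0)
        if n == 0:
            continue
        p_surv = design.survival_prob.get(group, 1.0)
        survived = rng.random(n) < p_surv
        tps = design.timepoints[:1] if group == "CNTRL" else design.timepoints
        for i in range(n):
            subject = f"{group}{i + 1:03d}"
            surv = "S" if survived[i] else "DNS"
            present = True
            for k, tp in enumerate(tps):
                if k > 0 and present:
                    p_drop = design.dropout_prob
                    if surv == "DNS" and tp in ("D5", "DC"):
                        p_drop = min(1.0, p_drop * design.nonsurvivor_dropout_factor)
                    if rng.random() < p_drop:
                        present = False
                if not present:
                    continue
                rows.append((f"{subject}_{tp}", subject, group, tp, surv))
    ann = pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "group", "timepoint", "survival"]
    ).set_index("sample_id")
    annotation = SampleAnnotation(ann)

    # --- probes ---------------------------------------------------------
    probe_ids, gene_ids = [], []
    for e in effects:
        if e.n_probes == 1:
            probe_ids.append(e.gene)
            gene_ids.append(e.gene)
        else:
            for j in range(e.n_probes):
                probe_ids.append(f"{e.gene}|p{j + 1}")
                gene_ids.append(e.gene)
    n_noise = design.n_probes - len(probe_ids)
    noise_ids = [f"P{j:05d}" for j in range(n_noise)]
    probe_ids += noise_ids
    gene_ids += noise_ids

    n_samples = len(ann)
    baseline = rng.normal(0.0, design.baseline_sd, size=design.n_probes)
    values = baseline[:, None] + rng.normal(
        0.0, design.probe_noise_sd, size=(design.n_probes, n_samples)
    )

    # --- planted shifts -------------------------------------------------
    tp_index = {tp: k for k, tp in enumerate(design.timepoints)}
    group_arr = ann["group"].to_numpy()
    tp_arr = ann["timepoint"].to_numpy()
    surv_arr = ann["survival"].to_numpy()
    row = 0
    for e in effects:
        in_group = np.isin(group_arr, list(e.affected_groups))
        mult = np.array([e.temporal_profile[tp_index[t]] for t in tp_arr])
        shift = np.where(in_group, e.log2_shift * mult, 0.0)
        if e.survival_modifier:
            shift = shift + np.where(in_group & (surv_arr == "DNS"), e.survival_modifier, 0.0)
        for _ in range(e.n_probes):
            values[row] += shift
            row += 1

    mat = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=ann.index),
        pd.Series(gene_ids, index=probe_ids),
    )
    return mat, annotation


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

INTEGER_VARS = ("SOFA", "APACHE_II", "Platelets")
_Z75 = norm.ppf(0.75)  # 0.67449


def lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Solve log-normal (mu, sigma) from a median and interquartile bounds.

    mu = ln median; sigma = (ln q3 - ln q1) / (2 z_0.75).  Non-positive lower
    quartiles (count data summarised as 0.00) are floored at median/10.
    """
    if median <= 0:
        raise ValueError("median must be > 0 for log-normal simulation")
    if q3 < q1:
        raise ValueError(f"inverted IQR bounds ({q1}, {q3})")
    if q1 == q3:
        return math.log(median), 0.0
    q1 = max(q1, median / 10.0)
    sigma = (math.log(q3) - math.log(q1)) / (2.0 * _Z75)
    return math.log(median), sigma


# Per-group clinical summaries: {(variable, timepoint): {group: (median, q1, q3)}}.
# CRP in mg/L; cell counts in 1e9/L; SOFA and APACHE II are unitless scores.
TABLE1_TARGETS = {
    ("APACHE_II", "D1"): {"SIRS": (30, 27, 34), "ABDM": (31, 24, 37), "PLMN": (31, 23, 40)},
    ("SOFA", "D1"): {"SIRS": (16, 14, 20), "ABDM": (17, 14, 19), "PLMN": (17, 15, 19)},
    ("SOFA", "D2"): {"SIRS": (17, 15, 18), "ABDM": (17, 14, 19), "PLMN": (16, 14, 18)},
    ("SOFA", "D5"): {"SIRS": (14, 11, 15), "ABDM": (14, 11, 18), "PLMN": (14, 12, 16)},
    ("SOFA", "DC"): {"SIRS": (9, 9, 11), "ABDM": (8, 7, 9), "PLMN": (9, 7, 10)},
    ("CRP", "D1"): {"SIRS": (26, 5, 51), "ABDM": (216, 104, 336), "PLMN": (197, 117, 280)},
    ("CRP", "D2"): {"SIRS": (131, 68, 170), "ABDM": (251, 113, 339), "PLMN": (201, 116, 273)},
    ("CRP", "D5"): {"SIRS": (138, 89, 175), "ABDM": (110, 56, 175), "PLMN": (94, 49, 163)},
    ("CRP", "DC"): {"SIRS": (80, 55, 179), "ABDM": (54, 25, 128), "PLMN": (48, 28, 124)},
    ("WBC", "D1"): {"SIRS": (14.9, 9.3, 21.2), "ABDM": (15.8, 11.7, 19.4), "PLMN": (15.8, 10.2, 22.4)},
    ("WBC", "D2"): {"SIRS": (10.4, 7.7, 15.5), "ABDM": (14.8, 9.8, 18.7), "PLMN": (15.1, 10.2, 19.6)},
    ("WBC", "D5"): {"SIRS": (9.8, 7.2, 12.4), "ABDM": (13.1, 11.0, 18.1), "PLMN": (11.8, 9.3, 16.4)},
    ("WBC", "DC"): {"SIRS": (10.7, 8.6, 12.5), "ABDM": (10.4, 8.1, 16.4), "PLMN": (10.1, 8.1, 13.0)},
    ("Neutrophils", "D1"): {"SIRS": (12.4, 7.3, 18.8), "ABDM": (12.8, 9.6, 17.3), "PLMN": (13.4, 8.6, 20.2)},
    ("Neutrophils", "D2"): {"SIRS": (8.5, 6.0, 12.5), "ABDM": (12.6, 8.5, 18.1), "PLMN": (12.5, 8.7, 18.1)},
    ("Neutrophils", "D5"): {"SIRS": (7.6, 5.7, 10.8), "ABDM": (10.7, 8.1, 15.1), "PLMN": (9.8, 6.8, 14.4)},
    ("Neutrophils", "DC"): {"SIRS": (8.6, 6.3, 10.4), "ABDM": (8.3, 6.5, 12.2), "PLMN": (7.4, 5.8, 8.8)},
    ("Lymphocytes", "D1"): {"SIRS": (1.0, 0.6, 1.5), "ABDM": (0.7, 0.5, 1.1), "PLMN": (0.6, 0.4, 1.0)},
    ("Lymphocytes", "D2"): {"SIRS": (0.9, 0.5, 1.3), "ABDM": (0.7, 0.5, 1.1), "PLMN": (0.8, 0.5, 1.2)},
    ("Lymphocytes", "D5"): {"SIRS": (0.8, 0.7, 1.2), "ABDM": (1.2, 0.9, 1.7), "PLMN": (1.1, 0.7, 1.4)},
    ("Lymphocytes", "DC"): {"SIRS": (1.3, 0.8, 1.8), "ABDM": (1.4, 1.1, 1.7), "PLMN": (1.2, 0.9, 2.1)},
    ("Basophils", "D1"): {"SIRS": (0.01, 0.00, 0.02), "ABDM": (0.01, 0.00, 0.01), "PLMN": (0.01, 0.00, 0.02)},
    ("Basophils", "D2"): {"SIRS": (0.01, 0.00, 0.20), "ABDM": (0.01, 0.00, 0.01), "PLMN": (0.01, 0.00, 0.10)},
    ("Basophils", "D5"): {"SIRS": (0.01, 0.00, 0.01), "ABDM": (0.01, 0.00, 0.10), "PLMN": (0.01, 0.00, 0.30)},
    ("Basophils", "DC"): {"SIRS": (0.01, 0.00, 0.02), "ABDM": (0.01, 0.00, 0.07), "PLMN": (0.02, 0.00, 0.10)},
    ("Platelets", "D1"): {"SIRS": (191, 158, 234), "ABDM": (205, 133, 301), "PLMN": (206, 143, 284)},
    ("Platelets", "D2"): {"SIRS": (143, 119, 209), "ABDM": (185, 106, 247), "PLMN": (159, 103, 245)},
    ("Platelets", "D5"): {"SIRS": (173, 157, 209), "ABDM": (192, 131, 278), "PLMN": (167, 99, 253)},
    ("Platelets", "DC"): {"SIRS": (212, 149, 284), "ABDM": (269, 166, 340), "PLMN": (282, 144, 417)},
}


def simulate_clinical(design: CohortDesign, annotation: SampleAnnotation,
                      targets=None, seed=None) -> pd.DataFrame:
    """Draw a clinical covariate table matched to per-group median/IQR targets.

    Each variable is log-normal with parameters solved by quantile matching
    (see lognormal_params).  Integer variables are rounded; SOFA is clipped
    to [0, 24]; APACHE II exists at D1 only.  Returns a DataFrame indexed by
    sample id, NaN where a variable does not apply.
    """
    if targets is None:
        targets = TABLE1_TARGETS
    for (var, tp), per_group in targets.items():
        if var == "APACHE_II" and tp != "D1":
            raise ValueError("APACHE II is a Day1-only score")
        for g, (med, q1, q3) in per_group.items():
            lognormal_params(med, q1, q3)  # validates, raises on inverted IQR
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)

    variables = sorted({var for var, _ in targets})
    table = pd.DataFrame(np.nan, index=annotation.table.index, columns=variables)
    group_arr = annotation.table["group"]
    tp_arr = annotation.table["timepoint"]
    for (var, tp), per_group in sorted(targets.items()):
        for g in sorted(per_group):
            med, q1, q3 = per_group[g]
            mu, sigma = lognormal_params(med, q1, q3)
            idx = table.index[(group_arr == g) & (tp_arr == tp)]
            if len(idx) == 0:
                continue
            if sigma == 0.0:
                draws = np.full(len(idx), float(med))
            else:
                draws = np.exp(mu + sigma * rng.standard_normal(len(idx)))
            if var in INTEGER_VARS:
                draws = np.round(draws)
            if var == "SOFA":
                draws = np.clip(draws, 0, 24)
            table.loc[idx, var] = draws
    return table


def realized_fold_change(matrix: ExpressionMatrix, annotation: SampleAnnotation,
                         gene: str, group_a, group_b, timepoint="D1") -> float:
    """Signed linear fold change of a gene between two groups at a timepoint.

    Multiple probes for the gene are collapsed by their per-sample mean before
    the group comparison (same signed-FC convention as diffstats.fold_change).
    """
    from .diffstats import fold_change

    probes = matrix.probes_for_gene(gene)
    if not probes:
        raise KeyError(f"gene {gene!r} not in matrix")
    sa = annotation.samples(groups=group_a, timepoint=timepoint)
    sb = annotation.samples(groups=group_b, timepoint=timepoint)
    if not sa or not sb:
        raise ValueError("empty group selection at this timepoint")
    vals = matrix.values.loc[probes]
    return fold_change(vals[sa].mean(axis=0).to_numpy(),
                       vals[sb].mean(axis=0).to_numpy())


# ---------------------------------------------------------------------------
# Preset planted-effect panels at published fold-change scale
# ---------------------------------------------------------------------------

# Inflammation indicators: upregulated in SIRS and sepsis vs healthy controls,
# Day1 linear fold changes at the scale of the published single-probe table.
_IOI_FC = {
    "CD177": 110.31, "FAM20A": 55.35, "MMP9": 45.49, "BMX": 28.57,
    "OLAH": 26.15, "HPR": 18.26, "IL1R2": 17.29, "ITGA7": 15.67,
    "TDRD9": 14.53, "ADM": 12.95, "IGFBP2": 12.73, "ALPL": 9.86,
    "CYP19A1": 9.68, "IL1R1": 8.25, "IL10": 7.06, "MMP8": 6.77,
    "DACH1": 5.73, "TGFA": 3.93, "VSTM1": 2.83,
}

# SIRS/sepsis discriminators: signed Day1 fold changes of sepsis vs SIRS
# (positive = up in sepsis).  MIA carries no published FC; planted mid-scale.
_SOS_FC = {
    "ITGB3": 7.47, "MYL9": 5.55, "PLXNB3": 5.10, "CETP": 4.95,
    "CMTM5": 4.93, "ITGA2B": 4.89, "MMRN1": 4.66, "PPBP": 4.36,
    "NEXN": 4.24, "TREML1": 4.10, "LCN2": 3.60, "PF4": 3.59,
    "MIA": 3.50, "LCN15": 2.02,
    "PLA2G7": -7.09, "ARHGEF10L": -3.86, "APCDD1": -3.66,
    "GPR124": -3.34, "MPP3": -3.28, "MYCL": -2.95,
}


def ioi_effects(genes=None) -> list[PlantedEffect]:
    """Planted inflammation-indicator effects (all disease groups vs controls)."""
    fc = _IOI_FC if genes is None else {g: _IOI_FC[g] for g in genes}
    return [PlantedEffect(g, DISEASE_GROUPS, v) for g, v in fc.items()]


def sos_effects(genes=None) -> list[PlantedEffect]:
    """Planted SIRS/sepsis discriminator effects (sepsis groups vs the rest)."""
    fc = _SOS_FC if genes is None else {g: _SOS_FC[g] for g in genes}
    return [PlantedEffect(g, SEPSIS_GROUPS, v) for g, v in fc.items()]
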