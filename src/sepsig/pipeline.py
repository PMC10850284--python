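"""End-to-end orchestration: simulate -> preprocess -> diffexp -> selection -> panels.

A run is driven by a YAML-style configuration mapping with one block per
stage; every stage writes plain TSV/JSON outputs into the run directory and
the run closes with a manifest (config echo, versions, seed, per-stage wall
time).  All stage randomness derives from the single global seed, so a rerun
with the same config is byte-identical apart from the manifest timestamps.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ann_select import AnnConfig, stepwise_select
from .diffstats import anova_qvalues, probe_stats_table
from .forest_rank import ForestConfig, iterative_eliminate, rank_importance
from .matrix import ExpressionMatrix, SampleAnnotation
from .panelroc import PanelDefinition, evaluate_panel, load_presets
from .preprocess import DEFAULT_BLACKLIST, run_preprocess
from .simcohort import (CohortDesign, PlantedEffect, generate_cohort,
                        ioi_effects, simulate_clinical, sos_effects)

logger = logging.getLogger("sepsig")

ALL_STAGES = ("simulate", "preprocess", "diffexp", "ann_select", "rf_rank", "panels")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Structured run configuration; see from_dict for the mapping layout."""

    outdir: str = "sepsig_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    cohort: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)      # matrix/annotation paths
    preprocess: dict = field(default_factory=dict)
    diffexp: dict = field(default_factory=dict)
    ann_select: dict = field(default_factory=dict)
    rf_rank: dict = field(default_factory=dict)
    panels: list = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for s in cfg.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if "simulate" not in cfg.stages:
            for key in ("matrix", "annotation"):
                path = cfg.inputs.get(key)
                if not path or not Path(path).exists():
                    raise ValueError(f"inputs.{key} required (and must exist) "
                                     "when the simulate stage is disabled")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _resolve_effects(spec) -> list:
    """Effect spec: 'ioi' / 'sos' presets or explicit mappings."""
    effects = []
    for item in spec:
        if item == "ioi":
            effects.extend(ioi_effects())
        elif item == "sos":
            effects.extend(sos_effects())
        elif isinstance(item, dict):
            effects.append(PlantedEffect(
                gene=item["gene"],
                affected_groups=tuple(item.get("groups", ("SIRS", "ABDM", "PLMN"))),
                fold_change=float(item["fold_change"]),
                **{k: item[k] for k in ("temporal_profile", "survival_modifier",
                                        "n_probes") if k in item}))
        else:
            raise ValueError(f"unrecognised effect spec {item!r}")
    return effects


def _gene_features(matrix: ExpressionMatrix, genes, samples) -> pd.DataFrame:
    """Samples x genes feature table; multi-probe genes collapse by mean."""
    cols = {}
    for g in genes:
        probes = matrix.probes_for_gene(g)
        if not probes:
            raise KeyError(f"gene {g!r} not in matrix")
        cols[g] = matrix.values.loc[probes, samples].mean(axis=0).to_numpy()
    return pd.DataFrame(cols, index=list(samples))


def _comparison_xy(matrix, annotation, block):
    pos = tuple(block.get("positive", ("ABDM", "PLMN")))
    neg = tuple(block.get("negative", ("SIRS",)))
    tp = block.get("timepoint", "D1")
    pos_ids = annotation.samples(groups=pos, timepoint=tp)
    neg_ids = annotation.samples(groups=neg, timepoint=tp)
    if not pos_ids or not neg_ids:
        raise ValueError("comparison groups empty at the requested timepoint")
    samples = pos_ids + neg_ids
    y = np.array([1] * len(pos_ids) + [0] * len(neg_ids))
    return samples, y, (pos, neg), tp


def _resolve_pool(spec, matrix) -> list:
    if spec in ("ioi", "sos"):
        preset = ioi_effects() if spec == "ioi" else sos_effects()
        return [e.gene for e in preset if matrix.probes_for_gene(e.gene)]
    return list(spec)


def _diag_dict(d):
    if d is None:
        return None
    out = asdict(d)
    out = {k: (list(v) if isinstance(v, tuple) else v) for k, v in out.items()}
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    logger.addHandler(handler)
    manifest = {"version": __version__, "seed": config.seed,
                "config": asdict(config), "stages": {}}
    matrix = annotation = None
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            t0 = time.perf_counter()
            logger.info("stage %s started", stage)
            try:
                if stage == "simulate":
                    block = dict(config.cohort)
                    effects = _resolve_effects(block.pop("effects", []))
                    design = CohortDesign(**block, seed=config.seed)
                    matrix, annotation = generate_cohort(design, effects)
                    clinical = simulate_clinical(design, annotation)
                    matrix.to_tsv(outdir / "matrix_raw.tsv")
                    annotation.to_tsv(outdir / "annotation.tsv")
                    clinical.to_csv(outdir / "clinical.tsv", sep="\t")
                elif stage == "preprocess":
                    if matrix is None:
                        matrix = ExpressionMatrix.from_tsv(config.inputs["matrix"])
                        annotation = SampleAnnotation.from_tsv(config.inputs["annotation"])
                    blk = config.preprocess
                    matrix, report = run_preprocess(
                        matrix, q=blk.get("q", 0.75), lo=blk.get("lo", -7.0),
                        hi=blk.get("hi", 7.0),
                        blacklist=blk.get("blacklist", DEFAULT_BLACKLIST))
                    matrix.to_tsv(outdir / "matrix_norm.tsv")
                    with open(outdir / "filter_report.json", "w") as fh:
                        json.dump({"n_before": report.n_before,
                                   "n_after": report.n_after,
                                   "removed_out_of_range": report.removed_out_of_range,
                                   "removed_blacklist": report.removed_blacklist},
                                  fh, indent=1)
                elif stage == "diffexp":
                    comparisons = config.diffexp.get("comparisons", [
                        {"name": "disease_vs_control", "a": ["SIRS", "ABDM", "PLMN"],
                         "b": ["CNTRL"], "timepoint": "D1"},
                        {"name": "sepsis_vs_sirs", "a": ["ABDM", "PLMN"],
                         "b": ["SIRS"], "timepoint": "D1"}])
                    for cmp_ in comparisons:
                        tab = probe_stats_table(matrix, annotation,
                                                tuple(cmp_["a"]), tuple(cmp_["b"]),
                                                timepoint=cmp_.get("timepoint"))
                        tab.to_csv(outdir / f"volcano_{cmp_['name']}.tsv", sep="\t")
                    if config.diffexp.get("anova", True):
                        groups = [g for g in ("CNTRL", "SIRS", "ABDM", "PLMN")
                                  if annotation.samples(groups=g)]
                        anova = anova_qvalues(matrix, annotation, groups)
                        anova.to_csv(outdir / "anova.tsv", sep="\t")
                elif stage == "ann_select":
                    block = config.ann_select
                    samples, y, _, _ = _comparison_xy(matrix, annotation, block)
                    pool = _resolve_pool(block.get("pool", "sos"), matrix)
                    cfg = AnnConfig(**block.get("config", {}), seed=config.seed)
                    X = _gene_features(matrix, pool, samples)
                    result = stepwise_select(pool, X, y, cfg)
                    result.to_tsv(outdir / "stepwise.tsv")
                    result.candidate_errors.to_csv(
                        outdir / "stepwise_candidates.tsv", sep="\t")
                elif stage == "rf_rank":
                    block = config.rf_rank
                    samples, y, _, _ = _comparison_xy(matrix, annotation, block)
                    genes = _resolve_pool(block.get("genes", "ioi"), matrix)
                    cfg = ForestConfig(**block.get("config", {}), seed=config.seed)
                    X = _gene_features(matrix, genes, samples)
                    imp = rank_importance(X, y, cfg)
                    imp.to_tsv(outdir / "importance.tsv")
                    target = block.get("target_size")
                    if target:
                        trace = iterative_eliminate(X, y, cfg, int(target))
                        trace.to_tsv(outdir / "elimination.tsv")
                        manifest["stages"].setdefault("rf_rank", {})
                elif stage == "panels":
                    summaries = {}
                    presets = load_presets()
                    for blk in config.panels:
                        spec = blk["panel"]
                        panel = presets[spec] if spec in presets \
                            else PanelDefinition.parse(spec)
                        samples, y, comparison, tp = _comparison_xy(
                            matrix, annotation, blk)
                        rep = evaluate_panel(panel, matrix, annotation,
                                             comparison, timepoint=tp)
                        key = blk.get("name", panel.name)
                        if rep.evaluated:
                            rep.scores.to_csv(outdir / f"scores_{key}.tsv", sep="\t")
                        summaries[key] = {
                            "panel": str(panel),
                            "comparison": [list(comparison[0]), list(comparison[1])],
                            "timepoint": tp,
                            "missing_genes": rep.missing_genes,
                            "auc": None if not rep.evaluated else rep.roc.auc,
                            "auc_se": None if not rep.evaluated else rep.roc.se,
                            "auc_ci90": None if not rep.evaluated else list(rep.roc.ci(0.90)),
                            "best": _diag_dict(rep.best),
                            "ppv_cutoff": rep.ppv_cutoff,
                            "npv_cutoff": rep.npv_cutoff,
                            "ppv": _diag_dict(rep.ppv_diag),
                            "npv": _diag_dict(rep.npv_diag),
                        }
                    with open(outdir / "panel_reports.json", "w") as fh:
                        json.dump(summaries, fh, indent=1)
            except Exception as exc:  # noqa: BLE001 - named-stage abort contract
                raise PipelineError(stage, exc) from exc
            manifest["stages"][stage] = {
                "wall_time_s": round(time.perf_counter() - t0, 3)}
            logger.info("stage %s finished", stage)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump({**manifest, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")},
                      fh, indent=1)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return manifest
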