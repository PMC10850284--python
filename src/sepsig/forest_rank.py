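"""Random-forest importance ranking and iterative least-important elimination.

The ensemble learner is delegated to scikit-learn (bagged CART trees with
per-split feature subsampling, i.e. a random forest); the module's own
content is the 75/25 split protocol, the dual importance report (OOB
permutation mean-decrease-accuracy plus Gini impurity decrease), and the
backward elimination loop that refits each round and drops the least
important gene until a target panel size remains.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

__all__ = ["ForestConfig", "ImportanceTable", "EliminationTrace",
           "rank_importance", "iterative_eliminate",
           "MTRY_INFLAMMATION", "MTRY_DISCRIMINATOR"]

# Per-split feature counts used for the two published panel sizes.
MTRY_INFLAMMATION = 31
MTRY_DISCRIMINATOR = 11


@dataclass
class ForestConfig:
    """n_trees=2001 matches the published runs; mtry=None -> floor(sqrt(p))."""

    n_trees: int = 2001
    mtry: int | None = None
    train_fraction: float = 0.75
    seed: int = 0

    def resolved_mtry(self, p: int) -> int:
        mtry = self.mtry if self.mtry is not None else max(1, int(math.sqrt(p)))
        if not 1 <= mtry:
            raise ValueError("mtry must be >= 1")
        return min(mtry, p)

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ImportanceTable:
    """Per-gene mean decrease in accuracy / Gini, plus OOB and test error."""

    table: pd.DataFrame  # index gene; columns mean_decrease_accuracy, mean_decrease_gini
    oob_error: float
    test_error: float

    def ranked(self, by: str = "mean_decrease_accuracy") -> pd.DataFrame:
        return self.table.sort_values(by, ascending=False)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


@dataclass
class EliminationTrace:
    rounds: list  # (retained gene tuple, oob_error) per refit
    final_panel: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_genes": [len(r[0]) for r in self.rounds],
             "oob_error": [r[1] for r in self.rounds],
             "retained": ["+".join(r[0]) for r in self.rounds]})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _fit_forest(Xtr: np.ndarray, ytr: np.ndarray, config: ForestConfig, mtry: int):
    tree = DecisionTreeClassifier(max_features=mtry)
    clf = BaggingClassifier(estimator=tree, n_estimators=config.n_trees,
                            bootstrap=True, oob_score=True,
                            random_state=config.seed % (2**32), n_jobs=1)
    clf.fit(Xtr, ytr)
    return clf


def _oob_permutation_importance(clf, Xtr: np.ndarray, ytr: np.ndarray,
                                rng: np.random.Generator) -> np.ndarray:
    """Mean over trees of the OOB accuracy drop when one feature is permuted.

    For each tree, its out-of-bag samples are predicted once unperturbed and
    once per feature with that feature's OOB column shuffled; the per-tree
    accuracy drops are averaged across trees.
    """
    n, p = Xtr.shape
    drops = np.zeros(p)
    n_used = 0
    for tree, inbag_idx in zip(clf.estimators_, clf.estimators_samples_):
        inbag = np.zeros(n, dtype=bool)
        inbag[inbag_idx] = True
        oob = np.flatnonzero(~inbag)
        if oob.size == 0:
            continue
        X_oob = Xtr[oob]
        y_oob = ytr[oob]
        # one stacked predict per tree: baseline block + one block per feature
        stacked = np.tile(X_oob, (p + 1, 1))
        for j in range(p):
            perm = rng.permutation(oob.size)
            stacked[(j + 1) * oob.size:(j + 2) * oob.size, j] = X_oob[perm, j]
        preds = tree.predict(stacked).reshape(p + 1, oob.size)
        base_acc = float(np.mean(preds[0] == y_oob))
        drops += base_acc - np.mean(preds[1:] == y_oob, axis=1)
        n_used += 1
    return drops / max(n_used, 1)


def rank_importance(X: pd.DataFrame, y, config: ForestConfig) -> ImportanceTable:
    """Fit on a stratified 75% training split; report both importances + errors.

    mean_decrease_accuracy is OOB permutation importance; mean_decrease_gini
    is the mean impurity decrease across trees.  test_error is the
    misclassification rate on the held-out 25%.
    """
    config.validate()
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    genes = list(X.columns)
    mtry = config.resolved_mtry(len(genes))
    Xa = X.to_numpy(dtype=float)
    Xtr, Xte, ytr, yte = train_test_split(
        Xa, y, train_size=config.train_fraction, stratify=y,
        random_state=config.seed % (2**32))
    clf = _fit_forest(Xtr, ytr, config, mtry)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                       spawn_key=(1,)))
    mda = _oob_permutation_importance(clf, Xtr, ytr, rng)
    gini = np.mean([t.feature_importances_ for t in clf.estimators_], axis=0)
    table = pd.DataFrame({"mean_decrease_accuracy": mda,
                          "mean_decrease_gini": gini}, index=genes)
    oob_error = 1.0 - float(clf.oob_score_)
    test_error = 1.0 - float(np.mean(clf.predict(Xte) == yte))
    return ImportanceTable(table, oob_error, test_error)


def iterative_eliminate(X: pd.DataFrame, y, config: ForestConfig,
                        target_size: int, drop_per_round: int = 1) -> EliminationTrace:
    """Refit-and-remove loop: drop the least important gene(s) each round.

    Each round refits rank_importance from scratch (no importance reuse) and
    removes the bottom drop_per_round genes by mean decrease in accuracy,
    breaking ties by gene id, until target_size genes remain.  The trace
    records every fit including the final panel's.
    """
    genes = list(X.columns)
    if not 0 < target_size < len(genes):
        raise ValueError("target_size must be in (0, n_genes)")
    rounds = []
    round_no = 0
    while True:
        cfg = replace(config, seed=config.seed + round_no)
        imp = rank_importance(X[genes], y, cfg)
        rounds.append((tuple(genes), imp.oob_error))
        if len(genes) == target_size:
            break
        n_drop = min(drop_per_round, len(genes) - target_size)
        order = sorted(genes, key=lambda g: (
            imp.table.loc[g, "mean_decrease_accuracy"], g))
        for g in order[:n_drop]:
            genes.remove(g)
        round_no += 1
    return EliminationTrace(rounds, list(genes))
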