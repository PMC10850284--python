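"""Stepwise neural-network feature selection with Monte-Carlo cross-validation.

The core bespoke algorithm: each candidate gene (alone, then appended to the
current best set) is scored by the mean blind-validation error of a small
logistic multilayer perceptron over R random stratified 60/20/20
train/test/validation splits, each with fresh weight initialization.  The
candidate with the lowest mean validation error is kept and the process
repeats until the panel stops improving or reaches its size cap.

The network is the classic three-layer perceptron of the microarray era:
two logistic hidden units, online backpropagation with momentum on a
squared-error loss, small-SD weight initialization and best-test-error
checkpointing, all of which act as regularisers against over-fitting at
microarray sample sizes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mlp import LOSS_MSE, LOSS_XENT, predict_kernel, train_kernel

__all__ = ["AnnConfig", "MlpModel", "StepwiseResult", "init_mlp", "train_mlp",
           "mc_error", "stepwise_select", "stability_runs"]


@dataclass
class AnnConfig:
    """Hyper-parameters of the stepwise MLP selection.

    Defaults follow the original protocol: 2 hidden nodes, learning rate 0.1,
    momentum 0.5, N(0, 0.1^2) initial weights, 60/20/20 splits repeated 50
    times.  The stopping tolerance for adding another gene and the epoch
    budget / patience are this package's choices (the protocol leaves them
    open); both are configurable.
    """

    n_hidden: int = 2
    learning_rate: float = 0.1
    momentum: float = 0.5
    init_sd: float = 0.1
    split_fractions: tuple = (0.6, 0.2, 0.2)
    n_resamples: int = 50
    max_epochs: int = 300
    patience: int = 20
    max_panel_size: int = 10
    improvement_tol: float = 1e-4
    loss: str = "mse"          # "mse" (classic backprop) or "xent"
    error_metric: str = "mse"  # validation ranking metric: "mse" or "mae"
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.split_fractions) <= 0:
            raise ValueError("split fractions must be positive")
        if self.learning_rate <= 0 or self.momentum < 0 or self.init_sd < 0:
            raise ValueError("learning_rate > 0, momentum >= 0, init_sd >= 0 required")
        if self.n_resamples < 1 or self.n_hidden < 1 or self.max_epochs < 1:
            raise ValueError("n_resamples, n_hidden, max_epochs must be >= 1")
        if self.loss not in ("mse", "xent") or self.error_metric not in ("mse", "mae"):
            raise ValueError("unknown loss or error metric")

    @property
    def _loss_kind(self) -> int:
        return LOSS_MSE if self.loss == "mse" else LOSS_XENT


@dataclass
class MlpModel:
    """input->hidden weights/biases and hidden->output weights/bias."""

    w1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[0]

    def forward(self, X) -> np.ndarray:
        """Logistic output in (0, 1) for each row of X."""
        X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
        return predict_kernel(self.w1, self.b1, self.w2, float(self.b2), X)

    def copy(self) -> "MlpModel":
        return MlpModel(self.w1.copy(), self.b1.copy(), self.w2.copy(), float(self.b2))


def init_mlp(n_inputs: int, config: AnnConfig, rng=None) -> MlpModel:
    """Fresh network: all weights N(0, init_sd^2), biases zero."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w1 = rng.normal(0.0, config.init_sd, size=(config.n_hidden, n_inputs))
    w2 = rng.normal(0.0, config.init_sd, size=config.n_hidden)
    return MlpModel(w1, np.zeros(config.n_hidden), w2, 0.0)


def train_mlp(model: MlpModel, X, y, config: AnnConfig, test=None,
              shuffle_seed: int | None = None) -> tuple[MlpModel, np.ndarray]:
    """Online backprop with momentum; returns (best-test-error model, trace).

    ``test`` is an optional (X_test, y_test) pair used for early stopping;
    without it the training split doubles as the test split.  The trace is
    the per-epoch test MSE up to the stopping epoch.
    """
    config.validate()
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite training inputs")
    if X.shape[0] != y.size:
        raise ValueError("X and y are misaligned")
    if test is None:
        Xte, yte = X, y
    else:
        Xte = np.ascontiguousarray(np.asarray(test[0], dtype=float))
        if Xte.ndim == 1:
            Xte = Xte[:, None]
        yte = np.asarray(test[1], dtype=float).ravel()
        if not (np.isfinite(Xte).all() and np.isfinite(yte).all()):
            raise ValueError("non-finite test inputs")
    if shuffle_seed is None:
        shuffle_seed = config.seed + 1
    m = model.copy()
    w1, b1, w2, b2, trace, n_epochs = train_kernel(
        m.w1, m.b1, m.w2, float(m.b2), X, y, Xte, yte,
        config.learning_rate, config.momentum, config.max_epochs,
        config.patience, config._loss_kind, int(shuffle_seed) & (2**64 - 1),
    )
    return MlpModel(w1, b1, w2, float(b2)), trace[:n_epochs]


def _stratified_split(y: np.ndarray, fractions, rng, max_redraws: int = 10):
    """Index triple (train, test, validation), stratified by class.

    Guarantees each split holds at least one member of every class (needs
    every class to have >= 3 samples); a draw that loses a class anyway is
    redrawn up to max_redraws times.
    """
    classes = np.unique(y)
    for cls in classes:
        if (y == cls).sum() < 3:
            raise ValueError("every class needs >= 3 samples for a 3-way split")
    for _ in range(max_redraws):
        tr, te, va = [], [], []
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            n = idx.size
            n_tr = int(round(fractions[0] * n))
            n_te = int(round(fractions[1] * n))
            n_tr = max(1, min(n_tr, n - 2))
            n_te = max(1, min(n_te, n - n_tr - 1))
            tr.append(idx[:n_tr])
            te.append(idx[n_tr:n_tr + n_te])
            va.append(idx[n_tr + n_te:])
        tr, te, va = (np.concatenate(s) for s in (tr, te, va))
        ok = all(np.intersect1d(split, np.flatnonzero(y == cls)).size > 0
                 for split in (tr, te, va) for cls in classes)
        if ok:
            return tr, te, va
        warnings.warn("split lost a class; redrawing")
    raise RuntimeError("could not draw a class-complete split")


def _resample_error(X, y, config, seed_key) -> float:
    """One Monte-Carlo resample: fresh split, fresh init, train, validate."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                       spawn_key=seed_key))
    tr, te, va = _stratified_split(y, config.split_fractions, rng)
    model = init_mlp(X.shape[1], config, rng=rng)
    shuffle_seed = int(rng.integers(1, 2**63))
    trained, _ = train_mlp(model, X[tr], y[tr], config,
                           test=(X[te], y[te]), shuffle_seed=shuffle_seed)
    pred = trained.forward(X[va])
    resid = pred - y[va]
    if config.error_metric == "mse":
        return float(np.mean(resid ** 2))
    return float(np.mean(np.abs(resid)))


def mc_error(candidate_genes, X: pd.DataFrame, y, config: AnnConfig,
             _seed_key=(0, 0)) -> float:
    """Mean blind-validation error of the candidate gene set over R resamples.

    X is samples x genes; candidate_genes selects columns.  Per-resample
    randomness is derived deterministically from config.seed.
    """
    config.validate()
    candidate_genes = list(candidate_genes)
    if not candidate_genes:
        raise ValueError("candidate set is empty")
    Xc = np.ascontiguousarray(X[candidate_genes].to_numpy(dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    errs = [
        _resample_error(Xc, y, config, seed_key=(*_seed_key, r))
        for r in range(config.n_resamples)
    ]
    return float(np.mean(errs))


@dataclass
class StepwiseResult:
    """Ordered selection with per-step errors and the full candidate tables."""

    selected: list
    step_errors: list
    candidate_errors: pd.DataFrame  # rows = steps, columns = pool genes

    def to_tsv(self, path) -> None:
        pd.DataFrame({"step": np.arange(1, len(self.selected) + 1),
                      "gene": self.selected,
                      "mean_val_error": self.step_errors}).to_csv(
            path, sep="\t", index=False)


def stepwise_select(pool, X: pd.DataFrame, y, config: AnnConfig) -> StepwiseResult:
    """Forward stepwise selection by minimum mean Monte-Carlo validation error.

    Step 1 scores every pool gene alone; step k scores every remaining gene
    appended to the current set.  Stops at max_panel_size or when the best
    new error fails to improve the previous step by >= improvement_tol.
    Ties break to the lexicographically smallest gene for reproducibility.
    """
    config.validate()
    pool = list(pool)
    if not pool:
        raise ValueError("empty gene pool")
    y = np.asarray(y, dtype=float).ravel()
    selected: list = []
    step_errors: list = []
    rows = []
    pool_pos = {g: i for i, g in enumerate(pool)}
    while len(selected) < min(config.max_panel_size, len(pool)):
        step = len(selected) + 1
        remaining = [g for g in pool if g not in selected]
        errors = {}
        for g in remaining:
            errors[g] = mc_error(selected + [g], X, y, config,
                                 _seed_key=(step, pool_pos[g]))
        best_gene = min(errors, key=lambda g: (errors[g], g))
        best_err = errors[best_gene]
        rows.append(errors)
        if step_errors and step_errors[-1] - best_err < config.improvement_tol:
            rows.pop()
            break
        selected.append(best_gene)
        step_errors.append(best_err)
    cand = pd.DataFrame(rows, columns=pool)
    cand.index = pd.RangeIndex(1, len(rows) + 1, name="step")
    return StepwiseResult(selected, step_errors, cand)


def stability_runs(pool, X: pd.DataFrame, y, config: AnnConfig,
                   n_runs: int = 10) -> pd.DataFrame:
    """Re-run the whole stepwise procedure across master seeds.

    Returns per-gene selection frequencies (any step, and as the first pick)
    over n_runs independent repetitions, to assess signature stability.
    """
    from dataclasses import replace

    pool = list(pool)
    counts = pd.DataFrame(0.0, index=pool, columns=["selected", "first_pick"])
    for run in range(n_runs):
        cfg = replace(config, seed=config.seed + 1009 * (run + 1))
        res = stepwise_select(pool, X, y, cfg)
        for g in res.selected:
            counts.loc[g, "selected"] += 1
        if res.selected:
            counts.loc[res.selected[0], "first_pick"] += 1
    return counts / n_runs
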