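"""Compiled inner loops for the small multilayer perceptron.

Online (per-sample) backpropagation with momentum on a logistic
input->hidden->output network, squared-error loss by default, with
best-test-error checkpointing.  Compiled with numba because the stepwise
selection evaluates on the order of 1e5 network fits per stability study.
"""
from __future__ import annotations

import numpy as np
from numba import njit

LOSS_MSE = 0
LOSS_XENT = 1


@njit(cache=True, inline="always")
def _xorshift(state: np.uint64) -> np.uint64:
    state ^= state << np.uint64(13)
    state ^= state >> np.uint64(7)
    state ^= state << np.uint64(17)
    return state


@njit(cache=True)
def _forward_batch(w1, b1, w2, b2, X, out):
    n, p = X.shape
    h = b1.shape[0]
    for i in range(n):
        acc = b2
        for j in range(h):
            z = b1[j]
            for m in range(p):
                z += w1[j, m] * X[i, m]
            acc += w2[j] * (1.0 / (1.0 + np.exp(-z)))
        out[i] = 1.0 / (1.0 + np.exp(-acc))


@njit(cache=True)
def train_kernel(w1, b1, w2, b2, Xtr, ytr, Xte, yte,
                 eta, alpha, max_epochs, patience, loss_kind, shuffle_seed):
    """Train in place; return (best_w1, best_b1, best_w2, best_b2, trace, n_epochs).

    trace holds the test-split MSE after each epoch (NaN beyond the last).
    The returned weights are those at the best test error (checkpointing).
    """
    n_tr, p = Xtr.shape
    h = b1.shape[0]

    vw1 = np.zeros_like(w1)
    vb1 = np.zeros_like(b1)
    vw2 = np.zeros_like(w2)
    vb2 = 0.0

    best_w1 = w1.copy()
    best_b1 = b1.copy()
    best_w2 = w2.copy()
    best_b2 = b2
    best_err = np.inf

    a = np.empty(h)
    order = np.arange(n_tr)
    te_out = np.empty(Xte.shape[0])
    trace = np.full(max_epochs, np.nan)

    state = np.uint64(shuffle_seed) | np.uint64(1)
    since_improve = 0
    n_epochs = 0
    for epoch in range(max_epochs):
        # Fisher-Yates shuffle of the sample order
        for i in range(n_tr - 1, 0, -1):
            state = _xorshift(state)
            j = int(state % np.uint64(i + 1))
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp

        for idx in range(n_tr):
            i = order[idx]
            # forward
            acc = b2
            for jh in range(h):
                z = b1[jh]
                for m in range(p):
                    z += w1[jh, m] * Xtr[i, m]
                a[jh] = 1.0 / (1.0 + np.exp(-z))
                acc += w2[jh] * a[jh]
            o = 1.0 / (1.0 + np.exp(-acc))
            # output delta: d(loss)/d(net_out)
            if loss_kind == LOSS_MSE:
                delta_o = (o - ytr[i]) * o * (1.0 - o)
            else:
                delta_o = o - ytr[i]
            # hidden deltas + updates with momentum
            for jh in range(h):
                delta_h = delta_o * w2[jh] * a[jh] * (1.0 - a[jh])
                dv = alpha * vw2[jh] - eta * delta_o * a[jh]
                vw2[jh] = dv
                w2[jh] += dv
                for m in range(p):
                    dw = alpha * vw1[jh, m] - eta * delta_h * Xtr[i, m]
                    vw1[jh, m] = dw
                    w1[jh, m] += dw
                db = alpha * vb1[jh] - eta * delta_h
                vb1[jh] = db
                b1[jh] += db
            dvb2 = alpha * vb2 - eta * delta_o
            vb2 = dvb2
            b2 += dvb2

        # test-split error for early stopping
        _forward_batch(w1, b1, w2, b2, Xte, te_out)
        err = 0.0
        for i in range(Xte.shape[0]):
            err += (te_out[i] - yte[i]) ** 2
        err /= max(Xte.shape[0], 1)
        trace[epoch] = err
        n_epochs = epoch + 1
        if err < best_err:
            best_err = err
            best_w1 = w1.copy()
            best_b1 = b1.copy()
            best_w2 = w2.copy()
            best_b2 = b2
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= patience:
                break

    return best_w1, best_b1, best_w2, best_b2, trace, n_epochs


@njit(cache=True)
def predict_kernel(w1, b1, w2, b2, X):
    out = np.empty(X.shape[0])
    _forward_batch(w1, b1, w2, b2, X, out)
    return out
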