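"""Symbolic-differentiation oracle for a single online backprop step."""
import numpy as np
import sympy as sp

from sepsig.ann_select import AnnConfig, init_mlp, train_mlp


def symbolic_matches_train_step(init_seed: int, x_val: float, y_val: float,
                                tol: float = 1e-12) -> bool:
    """One update on the 1-input/2-hidden/1-output logistic net equals the
    symbolic gradient step on 0.5*(y-o)^2."""
    cfg = AnnConfig(momentum=0.0, max_epochs=1, patience=5, seed=0)
    model = init_mlp(1, cfg, rng=np.random.default_rng(init_seed))

    x, y = sp.Symbol("x"), sp.Symbol("y")
    sig = lambda z: 1 / (1 + sp.exp(-z))
    syms = {f"{name}_{j}": sp.Symbol(f"{name}_{j}")
            for name in ("w1", "b1", "w2") for j in range(2)}
    syms["b2"] = sp.Symbol("b2")
    o = sig(syms["b2"] + sum(
        syms[f"w2_{j}"] * sig(syms[f"w1_{j}"] * x + syms[f"b1_{j}"])
        for j in range(2)))
    loss = sp.Rational(1, 2) * (y - o) ** 2

    subs = {x: x_val, y: y_val, syms["b2"]: model.b2}
    for j in range(2):
        subs[syms[f"w1_{j}"]] = model.w1[j, 0]
        subs[syms[f"b1_{j}"]] = model.b1[j]
        subs[syms[f"w2_{j}"]] = model.w2[j]
    expected = {
        name: float(subs[s]) - cfg.learning_rate * float(
            sp.diff(loss, s).evalf(30, subs=subs))
        for name, s in syms.items()
    }

    trained, _ = train_mlp(model, [[x_val]], [y_val], cfg)
    got = {"b2": trained.b2}
    for j in range(2):
        got[f"w1_{j}"] = trained.w1[j, 0]
        got[f"b1_{j}"] = trained.b1[j]
        got[f"w2_{j}"] = trained.w2[j]
    return all(abs(got[k] - expected[k]) < tol for k in expected)
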