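"""Comparison models: LASSO, SVR-RBF, and bidirectional RNN / LSTM.

LASSO and SVR consume the flattened token sequence through scikit-learn;
the recurrent baselines consume the per-timepoint token matrix (weather
channels per window, with the static context features broadcast to every
step) and are trained with plain NumPy backprop-through-time.  All models
share the transformer's splits and the package's single metrics
implementation, and select hyperparameters by validation RMSE over a small
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso
from sklearn.svm import SVR

from .nn import Adam, F32, glorot
from .tokens import TOKEN_DIM, TokenDataset

BASELINE_KINDS = ("lasso", "svr_rbf", "brnn", "blstm")


@dataclass
class BaselineSpec:
    kind: str
    grid: list[dict] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in BASELINE_KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if not self.grid:
            self.grid = default_grid(self.kind)


def default_grid(kind: str) -> list[dict]:
    if kind == "lasso":
        return [{"alpha": a} for a in (1e-4, 1e-3, 1e-2, 1e-1)]
    if kind == "svr_rbf":
        return [{"C": c, "gamma": g} for c in (1.0, 10.0, 100.0)
                for g in ("scale", 0.01)]
    # recurrent nets
    return [{"hidden": h, "lr": lr, "epochs": 40}
            for h in (24,) for lr in (3e-3, 1e-2)]


def flat_features(dataset: TokenDataset) -> np.ndarray:
    """Flattened token sequence, one row per record."""
    n = dataset.n
    return dataset.X.reshape(n, -1).astype(np.float64)


def sequence_features(dataset: TokenDataset) -> np.ndarray:
    """Per-timepoint matrix for the recurrent baselines.

    Shape (n, P, 6*3 + 4): the six weather variables' (max, min, mean)
    channels for each window, plus standardized latitude/longitude and the
    genotype-cluster and maturity codes repeated at every step.
    """
    lay = dataset.layout
    n, P = dataset.n, lay.n_timepoints
    w = dataset.X[:, : lay.n_weather_tokens].reshape(
        n, lay.n_variables, P, TOKEN_DIM)
    w = w.transpose(0, 2, 1, 3).reshape(n, P, lay.n_variables * TOKEN_DIM)
    ctx = np.stack([
        dataset.X[:, lay.loc_index, 0], dataset.X[:, lay.loc_index, 1],
        dataset.X[:, lay.geno_index, 0], dataset.X[:, lay.mg_index, 0]], axis=1)
    ctx = np.repeat(ctx[:, None, :], P, axis=1)
    return np.concatenate([w, ctx], axis=2).astype(np.float64)


# ---------------------------------------------------------------------------
# Recurrent baselines (NumPy BPTT)

class _BiRecurrent:
    """One-layer bidirectional recurrent regressor with a linear head on
    the concatenated final states of both directions."""

    cell = "rnn"

    def __init__(self, d_in: int, hidden: int, seed: int):
        rng = np.random.default_rng(seed)
        self.h = hidden
        gates = 4 if self.cell == "lstm" else 1
        def mk(shape):
            return glorot(rng, shape)
        self.params = {}
        for d in ("f", "b"):  # forward / backward direction
            self.params[f"Wx_{d}"] = mk((d_in, gates * hidden))
            self.params[f"Wh_{d}"] = mk((hidden, gates * hidden))
            self.params[f"b_{d}"] = np.zeros(gates * hidden, dtype=F32)
        self.params["Wo"] = mk((2 * hidden, 1))
        self.params["bo"] = np.zeros(1, dtype=F32)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    # -- single-direction passes ---------------------------------------
    def _run(self, x: np.ndarray, d: str):
        """x: (B, P, D) already direction-ordered; returns final state and
        cache for BPTT."""
        raise NotImplementedError

    def forward(self, x: np.ndarray):
        hf, cache_f = self._run(x, "f")
        hb, cache_b = self._run(x[:, ::-1], "b")
        hcat = np.concatenate([hf, hb], axis=1)
        y = hcat @ self.params["Wo"] + self.params["bo"]
        return y[:, 0], (x, hcat, cache_f, cache_b)

    def backward(self, dy: np.ndarray, cache) -> None:
        x, hcat, cache_f, cache_b = cache
        dy2 = dy[:, None]
        self.grads["Wo"] += hcat.T @ dy2
        self.grads["bo"] += dy2.sum(axis=0)
        dhcat = dy2 @ self.params["Wo"].T
        h = self.h
        self._bptt(dhcat[:, :h], cache_f, "f")
        self._bptt(dhcat[:, h:], cache_b, "b")

    def _bptt(self, dh_last, cache, d: str) -> None:
        raise NotImplementedError

    def zero_grad(self):
        for g in self.grads.values():
            g[...] = 0.0


class BiRNN(_BiRecurrent):
    """tanh Elman cell."""

    cell = "rnn"

    def _run(self, x, d):
        Wx, Wh, b = (self.params[f"Wx_{d}"], self.params[f"Wh_{d}"],
                     self.params[f"b_{d}"])
        B, P, _ = x.shape
        h = np.zeros((B, self.h), dtype=F32)
        hs, xs = [], []
        pre = x.astype(F32) @ Wx + b
        for t in range(P):
            h = np.tanh(pre[:, t] + h @ Wh)
            hs.append(h)
        return h, (x, hs)

    def _bptt(self, dh, cache, d):
        x, hs = cache
        Wx, Wh = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"]
        xd = x.astype(F32)
        P = xd.shape[1]
        dh = dh.astype(F32)
        for t in range(P - 1, -1, -1):
            dz = dh * (1.0 - hs[t] ** 2)
            self.grads[f"Wx_{d}"] += xd[:, t].T @ dz
            self.grads[f"b_{d}"] += dz.sum(axis=0)
            if t > 0:
                self.grads[f"Wh_{d}"] += hs[t - 1].T @ dz
                dh = dz @ Wh.T
            else:
                dh = None


class BiLSTM(_BiRecurrent):
    """Standard LSTM cell, gate order (i, f, g, o)."""

    cell = "lstm"

    def _run(self, x, d):
        Wx, Wh, b = (self.params[f"Wx_{d}"], self.params[f"Wh_{d}"],
                     self.params[f"b_{d}"])
        B, P, _ = x.shape
        H = self.h
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        pre_x = x.astype(F32) @ Wx + b
        steps = []
        for t in range(P):
            z = pre_x[:, t] + h @ Wh
            i = _sig(z[:, :H]); f = _sig(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H]); o = _sig(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            steps.append((i, f, g, o, c_prev, c, tc, h))
        return h, (x, steps)

    def _bptt(self, dh, cache, d):
        x, steps = cache
        Wh = self.params[f"Wh_{d}"]
        xd = x.astype(F32)
        P = xd.shape[1]
        H = self.h
        dh = dh.astype(F32)
        dc = np.zeros_like(dh)
        for t in range(P - 1, -1, -1):
            i, f, g, o, c_prev, c, tc, h = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc ** 2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.grads[f"Wx_{d}"] += xd[:, t].T @ dz
            self.grads[f"b_{d}"] += dz.sum(axis=0)
            if t > 0:
                h_prev = steps[t - 1][7]
                self.grads[f"Wh_{d}"] += h_prev.T @ dz
                dh = dz @ Wh.T
                dc = dc * f
            else:
                dh = None


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


class _RecurrentParamView:
    """Adapter so nn.Adam can drive the dict-based recurrent params."""

    def __init__(self, net):
        from .nn import Param
        self._net = net
        self.plist = []
        for k in net.params:
            p = Param.__new__(Param)
            p.value = net.params[k]
            p.grad = net.grads[k]
            p.name = k
            p.trainable = True
            self.plist.append(p)


def _train_recurrent(net, X, y, tr, va, lr, epochs, batch, seed):
    view = _RecurrentParamView(net)
    opt = Adam(view.plist, lr=lr)
    rng = np.random.default_rng(seed)
    best = (np.inf, {k: v.copy() for k, v in net.params.items()})
    for _ in range(epochs):
        order = rng.permutation(tr)
        for s in range(0, len(order), batch):
            idx = order[s:s + batch]
            net.zero_grad()
            yhat, cache = net.forward(X[idx])
            err = (yhat - y[idx]).astype(F32)
            net.backward((2.0 / len(idx)) * err, cache)
            opt.step()
        val_pred, _ = net.forward(X[va])
        v = float(np.mean((val_pred - y[va]) ** 2))
        if v < best[0]:
            best = (v, {k: vv.copy() for k, vv in net.params.items()})
    for k in net.params:
        net.params[k][...] = best[1][k]
    return best[0]


@dataclass
class FittedBaseline:
    kind: str
    chosen: dict
    predict: "callable"  # maps feature array -> trait-scale predictions


def fit_baseline(spec: BaselineSpec, dataset: TokenDataset, trait: str,
                 split: tuple[np.ndarray, np.ndarray, np.ndarray]) -> FittedBaseline:
    """Grid-search one baseline on the shared split; selection by
    validation RMSE on standardized targets."""
    tr, va, _te = split
    y_raw = dataset.traits[trait]
    stats = dataset.stats
    if trait not in stats.trait_mean:
        stats.fit_trait(trait, y_raw[tr])
    y = stats.standardize_trait(trait, y_raw)

    seq = spec.kind in ("brnn", "blstm")
    X = sequence_features(dataset) if seq else flat_features(dataset)

    best_rmse, best_fit, best_hp = np.inf, None, None
    for hp in spec.grid:
        if spec.kind == "lasso":
            est = Lasso(alpha=hp["alpha"], max_iter=5000)
            est.fit(X[tr], y[tr])
            pred = est.predict
        elif spec.kind == "svr_rbf":
            est = SVR(kernel="rbf", **hp)
            est.fit(X[tr], y[tr])
            pred = est.predict
        else:
            cls = BiRNN if spec.kind == "brnn" else BiLSTM
            net = cls(X.shape[2], hp["hidden"], seed=spec.seed)
            _train_recurrent(net, X, y, tr, va, hp["lr"], hp["epochs"],
                             batch=64, seed=spec.seed + 1)
            pred = lambda A, _n=net: _n.forward(A)[0]
        rmse = float(np.sqrt(np.mean((pred(X[va]) - y[va]) ** 2)))
        if rmse < best_rmse:
            best_rmse, best_fit, best_hp = rmse, pred, hp

    def predict(features: np.ndarray) -> np.ndarray:
        return stats.destandardize_trait(trait, np.asarray(best_fit(features)))

    return FittedBaseline(kind=spec.kind, chosen=dict(best_hp), predict=predict)
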