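"""Transformer encoder regressor for multi-environment trait prediction.

Each token of the input sequence (weather windows plus context) is embedded
by a shared linear projection — category tokens (genotype cluster, maturity
group) instead look up dedicated embedding tables — a learned positional
encoding is added, and N stacked encoder layers (multi-head self-attention
followed by a position-wise feedforward network) transform the sequence.
The final representations are flattened into a linear regression head that
predicts one standardized trait value; training minimizes mean squared
error with Adam, cosine learning-rate annealing and early stopping on a
validation split.

Transfer to data-scarce traits reuses a pretrained encoder either frozen
(only a fresh regression head trains) or fine-tuned end to end; "vanilla"
trains the same architecture from scratch as the no-transfer control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .nn import (Adam, Dropout, EncoderLayer, F32, LayerNorm, Linear, Param,
                 cosine_lr, glorot)
from .tokens import (CODE_OFFSET, MASK_CODE, TOKEN_DIM, TokenDataset,
                     TokenLayout, NormalizationStats)


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    Defaults are desk scale: the learning rate the source protocol used at
    full scale (5e-6) is far too small for the small synthetic datasets this
    package trains on, so 1e-3 with cosine decay is the default; both are
    plain config values.
    """

    d_model: int = 64
    n_layers: int = 4
    n_heads: int = 4
    d_ff: int = 128
    dropout: float = 0.1
    lr: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 20
    seed: int = 0
    positional: str = "learned"  # or "sinusoidal"
    #: LayerNorm on the embedded tokens before the encoder; equalizes token
    #: scale so attention reflects content rather than raw magnitude.
    embed_norm: bool = True

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be a probability")


@dataclass
class SplitSpec:
    """Record-level random train/validation/test partition."""

    train: float = 0.8
    val: float = 0.1
    test: float = 0.1
    seed: int = 0

    def indices(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if abs(self.train + self.val + self.test - 1.0) > 1e-8:
            raise ValueError("split fractions must sum to 1")
        perm = np.random.default_rng(self.seed).permutation(n)
        n_tr = int(round(self.train * n))
        n_va = int(round(self.val * n))
        tr, va, te = perm[:n_tr], perm[n_tr:n_tr + n_va], perm[n_tr + n_va:]
        if min(len(tr), len(va), len(te)) == 0:
            raise ValueError("a split partition is empty")
        return tr, va, te


def _sinusoidal(T: int, d: int) -> np.ndarray:
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(F32)


class TransformerRegressor:
    """The encoder regressor with attention exposure and input gradients."""

    def __init__(self, layout: TokenLayout, n_clusters: int, config: ModelConfig,
                 stats: NormalizationStats, trait: str):
        self.layout = layout
        self.config = config
        self.stats = stats
        self.trait = trait
        self.n_clusters = n_clusters
        rng = np.random.default_rng(config.seed)
        d = config.d_model
        T = layout.n_tokens
        self.proj = Linear(rng, TOKEN_DIM, d, "proj")
        # Embedding tables: row 0 = mask (pinned to zero), row 1 = unseen.
        self.emb_geno = Param(
            0.1 * rng.standard_normal((n_clusters + CODE_OFFSET, d)).astype(F32),
            "emb_geno")
        self.emb_mg = Param(
            0.1 * rng.standard_normal((10 + CODE_OFFSET, d)).astype(F32), "emb_mg")
        self.emb_geno.value[MASK_CODE] = 0.0
        self.emb_mg.value[MASK_CODE] = 0.0
        if config.positional == "learned":
            self.pos = Param(0.02 * rng.standard_normal((T, d)).astype(F32), "pos")
        else:
            self.pos = Param(_sinusoidal(T, d), "pos")
            self.pos.trainable = False
        self.encoder = [
            EncoderLayer(rng, d, config.n_heads, config.d_ff, config.dropout,
                         f"enc{i}") for i in range(config.n_layers)]
        self.head = Linear(rng, T * d, 1, "head")
        self.ln_in = LayerNorm(d, "ln_in") if config.embed_norm else None
        self.drop_in = Dropout(config.dropout)
        self.history: pd.DataFrame | None = None
        self._cache = None

    # -- parameter bookkeeping ------------------------------------------
    def params(self) -> list[Param]:
        ps = self.proj.params() + [self.emb_geno, self.emb_mg, self.pos]
        if self.ln_in is not None:
            ps += self.ln_in.params()
        for layer in self.encoder:
            ps += layer.params()
        return ps + self.head.params()

    def encoder_params(self) -> list[Param]:
        """Everything except the regression head."""
        return [p for p in self.params() if not p.name.startswith("head")]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]

    def reinit_head(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self.head.W.value[...] = glorot(rng, self.head.W.value.shape)
        self.head.b.value[...] = 0.0

    # -- forward / backward ---------------------------------------------
    def embed(self, X: np.ndarray) -> np.ndarray:
        """Pre-positional token embeddings, shape (B, T, d_model)."""
        X = np.asarray(X, dtype=F32)
        lay = self.layout
        e = X @ self.proj.W.value + self.proj.b.value
        for idx, table in ((lay.geno_index, self.emb_geno),
                           (lay.mg_index, self.emb_mg)):
            codes = np.clip(X[:, idx, 0].round().astype(int), 0,
                            table.value.shape[0] - 1)
            e[:, idx, :] = table.value[codes]
        self._embed_cache = (X, {lay.geno_index: None, lay.mg_index: None})
        return e

    def forward_embedded(self, e: np.ndarray, train: bool = False,
                         rng: np.random.Generator | None = None) -> np.ndarray:
        """Run encoder + head from pre-positional embeddings.

        Returns standardized-trait predictions, shape (B,)."""
        z = e + self.pos.value
        if self.ln_in is not None:
            z = self.ln_in.forward(z)
        z = self.drop_in.forward(z, train, rng)
        for layer in self.encoder:
            z = layer.forward(z, train, rng)
        B, T, d = z.shape
        out = self.head.forward(z.reshape(B, T * d))[:, 0]
        self._shape = (B, T, d)
        return out

    def backward_embedded(self, dy: np.ndarray) -> np.ndarray:
        """Backprop dL/dy through head and encoder; returns dL/de where e is
        the pre-positional embedded input.  Accumulates parameter grads."""
        B, T, d = self._shape
        dz = self.head.backward(dy[:, None]).reshape(B, T, d)
        for layer in reversed(self.encoder):
            dz = layer.backward(dz)
        dz = self.drop_in.backward(dz)
        if self.ln_in is not None:
            dz = self.ln_in.backward(dz)
        self.pos.grad += dz.sum(axis=0)
        return dz

    def backward_to_params(self, dy: np.ndarray) -> None:
        """Finish backprop into projection and embedding tables."""
        de = self.backward_embedded(dy)
        X, _ = self._embed_cache
        lay = self.layout
        cont = np.ones(lay.n_tokens, dtype=bool)
        cont[[lay.geno_index, lay.mg_index]] = False
        dcont = de[:, cont, :]
        xcont = X[:, cont, :]
        self.proj.W.grad += xcont.reshape(-1, TOKEN_DIM).T @ dcont.reshape(-1, de.shape[-1])
        self.proj.b.grad += dcont.reshape(-1, de.shape[-1]).sum(axis=0)
        for idx, table in ((lay.geno_index, self.emb_geno),
                           (lay.mg_index, self.emb_mg)):
            codes = np.clip(X[:, idx, 0].round().astype(int), 0,
                            table.value.shape[0] - 1)
            np.add.at(table.grad, codes, de[:, idx, :])
        # mask row stays a true zero token
        self.emb_geno.grad[MASK_CODE] = 0.0
        self.emb_mg.grad[MASK_CODE] = 0.0

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                token_scale: np.ndarray | None = None) -> np.ndarray:
        """Standardized-trait predictions for a batch of token matrices.

        ``token_scale`` (per-token, broadcast over channels) scales the
        embedded tokens before the positional encoding is added; it is the
        hook used by masking-based perturbation and attribution paths.
        """
        e = self.embed(X)
        if token_scale is not None:
            e = e * np.asarray(token_scale, dtype=F32)[..., None]
        return self.forward_embedded(e, train, rng)

    def predict(self, X: np.ndarray, batch_size: int = 256,
                token_scale: np.ndarray | None = None) -> np.ndarray:
        """Deterministic trait-scale predictions."""
        outs = []
        for s in range(0, len(X), batch_size):
            sl = slice(s, s + batch_size)
            ts = None if token_scale is None else token_scale[sl]
            outs.append(self.forward(X[sl], train=False, token_scale=ts))
        yhat = np.concatenate(outs) if outs else np.empty(0)
        return self.stats.destandardize_trait(self.trait, yhat.astype(np.float64))

    def attention_maps(self, X: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Attention tensors for each sample: (B, n_layers, n_heads, T, T)."""
        maps = []
        for s in range(0, len(X), batch_size):
            self.forward(X[s:s + batch_size], train=False)
            maps.append(np.stack([layer.mha.attn for layer in self.encoder], axis=1))
        return np.concatenate(maps, axis=0)

    def input_gradient(self, e: np.ndarray) -> np.ndarray:
        """d(prediction)/d(embedded tokens), summed over the batch outputs.

        Runs a fresh forward from embeddings ``e`` in eval mode; parameter
        gradients accumulated as a side effect are discarded by callers.
        """
        self.forward_embedded(e, train=False)
        return self.backward_embedded(np.ones(e.shape[0], dtype=F32))


@dataclass
class TrainResult:
    model: TransformerRegressor
    split: tuple[np.ndarray, np.ndarray, np.ndarray]
    history: pd.DataFrame
    n_excluded: int


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def train_model(
    dataset: TokenDataset,
    trait: str,
    config: ModelConfig,
    split: SplitSpec | tuple[np.ndarray, np.ndarray, np.ndarray],
    model: TransformerRegressor | None = None,
    trainable: str = "all",
    verbose: bool = False,
) -> TrainResult:
    """Fit a transformer regressor on one trait.

    Records missing the trait are excluded (count reported in the result).
    ``trainable='head'`` freezes everything except the regression head.
    The best-validation parameters are restored at the end.
    """
    y_raw = dataset.traits[trait]
    present = ~np.isnan(y_raw)
    n_excluded = int((~present).sum())
    keep = np.flatnonzero(present)
    X, y_kept = dataset.X[keep], y_raw[keep]

    if isinstance(split, SplitSpec):
        tr, va, te = split.indices(len(keep))
    else:
        tr, va, te = split
    if min(len(tr), len(va)) == 0:
        raise ValueError("empty train or validation partition")

    stats = dataset.stats
    stats.fit_trait(trait, y_kept[tr])
    y = stats.standardize_trait(trait, y_kept).astype(F32)

    if model is None:
        model = TransformerRegressor(dataset.layout, dataset.n_clusters, config,
                                     stats, trait)
    params = model.params() if trainable == "all" else model.head.params()
    frozen = [] if trainable == "all" else [p for p in model.params()
                                            if p not in params]
    opt = Adam(params, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)

    best_val, best_state, best_epoch = np.inf, model.state_dict(), -1
    hist = []
    for epoch in range(config.max_epochs):
        lr = cosine_lr(epoch, config.max_epochs, config.lr)
        order = rng.permutation(tr)
        losses = []
        for s in range(0, len(order), config.batch_size):
            idx = order[s:s + config.batch_size]
            opt.zero_grad()
            yhat = model.forward(X[idx], train=True, rng=rng)
            err = yhat - y[idx]
            losses.append(float(np.mean(err ** 2)))
            model.backward_to_params((2.0 / len(idx)) * err.astype(F32))
            opt.step(lr)
        val_pred = np.concatenate([
            model.forward(X[va[s:s + 256]]) for s in range(0, len(va), 256)])
        val_loss = _mse(val_pred, y[va])
        hist.append({"epoch": epoch, "lr": lr,
                     "train_loss": float(np.mean(losses)), "val_loss": val_loss})
        if verbose:
            print(f"epoch {epoch:3d} lr {lr:.2e} train {np.mean(losses):.4f} "
                  f"val {val_loss:.4f}")
        if val_loss < best_val - 1e-7:
            best_val, best_state, best_epoch = val_loss, model.state_dict(), epoch
        elif epoch - best_epoch >= config.patience:
            break
    model.load_state_dict(best_state)
    model.history = pd.DataFrame(hist)
    split_global = tuple(keep[s] for s in (tr, va, te))
    return TrainResult(model=model, split=(tr, va, te), history=model.history,
                       n_excluded=n_excluded)


def transfer(
    pretrained: TransformerRegressor | None,
    dataset: TokenDataset,
    target_trait: str,
    mode: str,
    config: ModelConfig,
    split: SplitSpec | tuple[np.ndarray, np.ndarray, np.ndarray],
) -> TrainResult:
    """Encoder-transfer strategies for data-scarce traits.

    - ``vanilla``: fresh model, trained end to end (no pretraining).
    - ``frozen``: pretrained encoder copied and frozen; only a freshly
      initialized regression head trains.
    - ``finetune``: pretrained encoder copied; everything (with a fresh
      head) trains end to end.
    """
    if mode not in ("vanilla", "frozen", "finetune"):
        raise ValueError(f"unknown transfer mode {mode!r}")
    if mode == "vanilla":
        return train_model(dataset, target_trait, config, split)
    if pretrained is None:
        raise ValueError(f"{mode} transfer requires a pretrained model")
    model = TransformerRegressor(dataset.layout, pretrained.n_clusters, config,
                                 dataset.stats, target_trait)
    state = pretrained.state_dict()
    for p in model.params():
        if not p.name.startswith("head") and p.name in state:
            p.value[...] = state[p.name]
    model.reinit_head(config.seed + 17)
    trainable = "head" if mode == "frozen" else "all"
    return train_model(dataset, target_trait, config, split, model=model,
                       trainable=trainable)


# ---------------------------------------------------------------------------
# Checkpoint round-trip

def save_model(model: TransformerRegressor, path) -> None:
    """Persist parameters + config + normalization stats as .npz."""
    meta = {
        "config": asdict(model.config),
        "trait": model.trait,
        "n_clusters": model.n_clusters,
        "layout": {"n_timepoints": model.layout.n_timepoints,
                   "interval_days": model.layout.interval_days},
        "stats": {
            "weather_mean": model.stats.weather_mean.tolist(),
            "weather_sd": model.stats.weather_sd.tolist(),
            "loc_mean": model.stats.loc_mean.tolist(),
            "loc_sd": model.stats.loc_sd.tolist(),
            "trait_mean": model.stats.trait_mean,
            "trait_sd": model.stats.trait_sd,
        },
    }
    arrays = {k.replace(".", "__"): v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> TransformerRegressor:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    stats = NormalizationStats(
        weather_mean=np.array(meta["stats"]["weather_mean"]),
        weather_sd=np.array(meta["stats"]["weather_sd"]),
        loc_mean=np.array(meta["stats"]["loc_mean"]),
        loc_sd=np.array(meta["stats"]["loc_sd"]),
        trait_mean=meta["stats"]["trait_mean"],
        trait_sd=meta["stats"]["trait_sd"])
    layout = TokenLayout(**meta["layout"])
    model = TransformerRegressor(layout, meta["n_clusters"],
                                 ModelConfig(**meta["config"]), stats, meta["trait"])
    model.load_state_dict(
        {k.replace("__", "."): data[k] for k in data.files if k != "__meta__"})
    return model
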