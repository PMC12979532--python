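"""Per-token importance scores for the trained transformer.

Two families of explainers are provided:

* **Attention aggregation** — attention maps from every encoder layer and
  head are mean-aggregated; a token's importance is the average attention
  it *receives* (column mean of each T×T map), renormalized to sum to 1.
* **Attribution adapters** — Integrated Gradients, GradientSHAP and LIME,
  computed in the model's embedded token space (the straight-line path
  from a zero token embedding to the sample's embedding), with per-channel
  attributions pooled by absolute value into one score per token.

All scores are nonnegative and normalized to sum to 1 so that methods are
comparable and directly consumable by the faithfulness evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import TransformerRegressor
from .nn import F32
from .tokens import TokenLayout, TokenSequence


class CapabilityError(RuntimeError):
    """An attribution backend that is not available in this build."""


ATTRIBUTION_METHODS = ("integrated_gradients", "gradient_shap", "lime")
UNAVAILABLE_METHODS = ("deeplift",)  # requires an external adapter


@dataclass
class ImportanceScores:
    """Normalized per-token relevance from one explainer on one sample."""

    scores: np.ndarray
    method: str
    sample_id: str = ""

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if np.any(s < 0):
            raise ValueError("importance scores must be nonnegative")
        total = s.sum()
        self.scores = s / total if total > 0 else np.full(s.size, 1.0 / s.size)

    @property
    def T(self) -> int:
        return self.scores.size


# ---------------------------------------------------------------------------
# Attention-based importance

def aggregate_attention_maps(maps: np.ndarray) -> np.ndarray:
    """Collapse (..., T, T) attention maps into per-token importance.

    A token's raw importance is the attention it receives (column mean of
    each map), mean-aggregated over all leading axes (layers, heads), then
    renormalized to sum to 1.
    """
    received = maps.mean(axis=tuple(range(maps.ndim - 1)))
    return received / received.sum()


def attention_importance(model: TransformerRegressor, sequence: TokenSequence,
                         sample_id: str = "") -> ImportanceScores:
    """Mean attention received per token, averaged over layers and heads."""
    maps = model.attention_maps(sequence.tokens[None])[0]  # (L, H, T, T)
    return ImportanceScores(scores=aggregate_attention_maps(maps),
                            method="attention", sample_id=sample_id)


def attention_importance_batch(model: TransformerRegressor, X: np.ndarray,
                               batch_size: int = 64) -> np.ndarray:
    """Vectorized attention importance for many samples: (n, T), rows sum 1."""
    out = []
    for s in range(0, len(X), batch_size):
        model.forward(X[s:s + batch_size], train=False)
        maps = np.stack([layer.mha.attn for layer in model.encoder], axis=1)
        rec = maps.mean(axis=(1, 2, 3))
        out.append(rec / rec.sum(axis=1, keepdims=True))
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Generic integrated gradients (used directly in tests and by the adapter)

def integrated_gradients(f, grad_f, x: np.ndarray, baseline: np.ndarray | None = None,
                         steps: int = 64) -> np.ndarray:
    """IG along the straight path baseline -> x for a scalar function.

    ``grad_f(x)`` must return d f / d x at ``x`` with x's shape.  Uses the
    midpoint rule, which converges to the path integral and satisfies
    completeness up to quadrature error.
    """
    if baseline is None:
        baseline = np.zeros_like(x)
    diff = x - baseline
    total = np.zeros_like(x, dtype=float)
    for a in (np.arange(steps) + 0.5) / steps:
        total += grad_f(baseline + a * diff)
    return diff * total / steps


def _model_embedding(model: TransformerRegressor, sequence: TokenSequence):
    e = model.embed(np.asarray(sequence.tokens, dtype=F32)[None])
    return e  # (1, T, d_model)


def ig_attribution(model: TransformerRegressor, sequence: TokenSequence,
                   steps: int = 64) -> tuple[np.ndarray, float, float]:
    """Integrated gradients along the path from the all-zero token matrix.

    The baseline is the *embedded* all-zero token matrix (zeroed weather
    channels, reserved mask code for the category tokens).  Quadrature is
    midpoint under the substitution alpha = t^2: near the baseline the
    embedding LayerNorm makes the path stiff (token variance is small and
    gradients large), and the substitution concentrates nodes there while
    damping them with the 2t weight.
    Returns (signed channel attributions (T, d_model), f(x), f(baseline)),
    on the standardized-trait scale.
    """
    e = _model_embedding(model, sequence).astype(np.float64)
    base = model.embed(np.zeros_like(sequence.tokens, dtype=F32)[None]
                       ).astype(np.float64)
    diff = e - base
    grads = np.zeros_like(e)
    for t in (np.arange(steps) + 0.5) / steps:
        grads += 2.0 * t * model.input_gradient(
            (base + (t * t) * diff).astype(F32))
    attr = diff[0] * grads[0] / steps
    fx = float(model.forward_embedded(e.astype(F32))[0])
    f0 = float(model.forward_embedded(base.astype(F32))[0])
    return attr, fx, f0


def gradient_shap_attribution(model: TransformerRegressor, sequence: TokenSequence,
                              n_samples: int = 32, noise_sd: float = 0.5,
                              seed: int = 0) -> np.ndarray:
    """Expected-gradients estimate: Gaussian baselines centered on the
    embedded all-zero token matrix."""
    e = _model_embedding(model, sequence).astype(np.float64)
    base = model.embed(np.zeros_like(sequence.tokens, dtype=F32)[None]
                       ).astype(np.float64)
    rng = np.random.default_rng(seed)
    attr = np.zeros(e.shape[1:], dtype=np.float64)
    for _ in range(n_samples):
        b = base + rng.normal(0.0, noise_sd, size=e.shape)
        a = rng.random()
        point = (b + a * (e - b)).astype(F32)
        g = model.input_gradient(point)[0].astype(np.float64)
        attr += (e - b)[0] * g
    return attr / n_samples


def lime_attribution(model: TransformerRegressor, sequence: TokenSequence,
                     n_samples: int = 256, seed: int = 0,
                     ridge: float = 1e-3) -> np.ndarray:
    """Local linear surrogate over random token masks.

    Tokens are switched off by zeroing their embedding (the model's neutral
    token); a weighted ridge regression of the perturbed predictions on the
    binary keep-mask gives one coefficient per token.
    """
    T = sequence.layout.n_tokens
    rng = np.random.default_rng(seed)
    masks = (rng.random((n_samples, T)) < 0.5).astype(F32)
    masks[0] = 1.0  # anchor at the full input
    X = np.repeat(sequence.tokens[None].astype(F32), n_samples, axis=0)
    preds = []
    for s in range(0, n_samples, 128):
        preds.append(model.forward(X[s:s + 128], token_scale=masks[s:s + 128]))
    y = np.concatenate(preds).astype(np.float64)
    frac_on = masks.mean(axis=1)
    w = np.exp(-((1.0 - frac_on) ** 2) / 0.25)  # proximity kernel
    Z = np.column_stack([np.ones(n_samples), masks.astype(np.float64)])
    WZ = Z * w[:, None]
    coef = np.linalg.solve(Z.T @ WZ + ridge * np.eye(T + 1), WZ.T @ y)
    return coef[1:]


def attribution(model: TransformerRegressor, sequence: TokenSequence,
                method: str, sample_id: str = "", steps: int = 64,
                seed: int = 0) -> ImportanceScores:
    """Per-token attribution scores: |channel attributions| summed per token,
    normalized to sum to 1."""
    if method in UNAVAILABLE_METHODS:
        raise CapabilityError(
            f"attribution method {method!r} requires an external adapter "
            "that is not available in this build")
    if method == "integrated_gradients":
        attr, _, _ = ig_attribution(model, sequence, steps=steps)
        per_token = np.abs(attr).sum(axis=1)
    elif method == "gradient_shap":
        attr = gradient_shap_attribution(model, sequence, seed=seed)
        per_token = np.abs(attr).sum(axis=1)
    elif method == "lime":
        per_token = np.abs(lime_attribution(model, sequence, seed=seed))
    else:
        raise ValueError(f"unknown attribution method {method!r}")
    return ImportanceScores(scores=per_token, method=method, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Aggregations over samples (variable/timepoint profiles etc.)

def scores_table(scores: list[ImportanceScores], layout: TokenLayout) -> pd.DataFrame:
    """Long-format table: sample, method, token, kind, variable, timepoint,
    score."""
    meta = layout.meta_frame()
    frames = []
    for s in scores:
        if s.T != layout.n_tokens:
            raise ValueError("importance scores do not match the token layout")
        df = meta.copy()
        df["score"] = s.scores
        df["method"] = s.method
        df["sample"] = s.sample_id
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def aggregate_importance(scores: list[ImportanceScores], layout: TokenLayout,
                         group_by: str,
                         sample_meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Group mean importance with standard errors.

    ``group_by``:
      - ``variable_timepoint``: mean score per (weather variable, window),
        context tokens reported as their own rows;
      - ``weather_vs_context``: per sample, all weather-token scores are
        summed into one composite value and compared with the three context
        tokens;
      - ``maturity_group``: per-variable mean scores within each maturity
        group (requires ``sample_meta`` with a ``maturity_group`` column
        aligned with the score list).
    """
    table = scores_table(scores, layout)
    if group_by == "variable_timepoint":
        g = table.groupby(["variable", "timepoint"])["score"]
    elif group_by == "weather_vs_context":
        is_w = table["kind"] == "weather"
        per = table.assign(group=np.where(is_w, "weather", table["kind"]))
        per = per.groupby(["sample", "method", "group"])["score"].sum().reset_index()
        g = per.groupby("group")["score"]
    elif group_by == "maturity_group":
        if sample_meta is None or "maturity_group" not in sample_meta:
            raise ValueError("maturity_group aggregation needs sample metadata")
        mg = {str(s.sample_id): m for s, m in
              zip(scores, sample_meta["maturity_group"])}
        table["maturity_group"] = table["sample"].astype(str).map(mg)
        g = table.groupby(["maturity_group", "variable"])["score"]
    else:
        raise ValueError(f"unknown grouping {group_by!r}")
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "score_mean", "sem": "score_sem",
                               "count": "n"})


# ---------------------------------------------------------------------------
# Reference explainers for recovery experiments

def oracle_scores(layout: TokenLayout, causal_windows, n_days: int,
                  sample_id: str = "") -> ImportanceScores:
    """Ground-truth explainer: uniform mass on tokens overlapping a planted
    causal window, zero elsewhere."""
    s = np.zeros(layout.n_tokens)
    iv = layout.interval_days
    for var, start, end, _w in causal_windows:
        for tp in range(layout.n_timepoints):
            lo, hi = tp * iv, min((tp + 1) * iv, n_days)
            if lo < end and start < hi:
                s[layout.token_index(var, tp)] = 1.0
    return ImportanceScores(scores=s, method="oracle", sample_id=sample_id)


def random_scores(layout: TokenLayout, seed: int,
                  sample_id: str = "") -> ImportanceScores:
    rng = np.random.default_rng(seed)
    return ImportanceScores(scores=rng.random(layout.n_tokens),
                            method="random", sample_id=sample_id)
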