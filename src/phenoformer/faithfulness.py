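"""Perturbation-based faithfulness evaluation of token importance.

For each perturbation level k (a percentage of the sequence), the top-k
tokens by an explainer's ranking are masked (*comprehensiveness*) or are
the only tokens kept (*sufficiency*); the shift between the unperturbed and
perturbed predictions, summarized as MAE and MSE over the evaluation
samples, quantifies how faithful the explanation is to the model.  The
per-level deltas are aggregated into the Area Over the Perturbation Curve
for Regression (AOPCR) by an unweighted mean across levels.

A faithful explainer has a *high* comprehensiveness AOPCR (masking its top
tokens hurts) and a *low* sufficiency AOPCR (its top tokens alone nearly
reproduce the prediction).  Masked tokens become the model's neutral
zero-embedding token; deltas are computed on the trait scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .interpret import ImportanceScores
from .model import TransformerRegressor
from .tokens import TokenSequence

DEFAULT_LEVELS = (5.0, 7.5, 10.0, 15.0, 25.0)


@dataclass
class PerturbationLevels:
    levels: tuple[float, ...] = DEFAULT_LEVELS

    def __post_init__(self):
        lv = tuple(float(x) for x in self.levels)
        if not lv or any(not 0 < x <= 100 for x in lv):
            raise ValueError("levels must lie in (0, 100]")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("levels must be strictly increasing")
        self.levels = lv


@dataclass
class FaithfulnessReport:
    method: str
    n_samples: int
    levels: tuple[float, ...]
    #: per-level mean deltas, keyed "comprehensiveness"/"sufficiency" ->
    #: {"mae": [...], "mse": [...]}
    per_level: dict = field(default_factory=dict)
    #: AOPCR per (setting, metric) pair
    aopcr: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @staticmethod
    def from_json(s: str) -> "FaithfulnessReport":
        d = json.loads(s)
        d["levels"] = tuple(d["levels"])
        return FaithfulnessReport(**d)


def rank_tokens(scores: ImportanceScores) -> np.ndarray:
    """Descending importance order; ties broken by ascending token index."""
    s = scores.scores
    # stable sort on negated scores keeps ascending index within ties
    return np.argsort(-s, kind="stable")


def n_masked(k_percent: float, T: int) -> int:
    """Number of tokens a level touches: round(k% of T), at least 1."""
    return max(1, int(round(k_percent / 100.0 * T)))


def perturb(sequence: TokenSequence, ranking: np.ndarray, k_percent: float,
            setting: str, maskable: np.ndarray | None = None
            ) -> tuple[TokenSequence, np.ndarray]:
    """Mask tokens per the setting; returns (sequence copy, keep-scale).

    The keep-scale is the per-token 0/1 vector actually consumed by the
    model (0 = replaced by the neutral zero-embedding token); the returned
    sequence has the masked token values zeroed for inspection, with
    metadata (the layout) untouched.

    ``maskable`` (boolean, length T) optionally restricts the evaluation to
    a token subset — e.g. weather tokens only, leaving context tokens
    always intact; the level then counts a percentage of the maskable
    tokens, and ``ranking`` entries outside the subset are ignored.
    """
    if not 0 < k_percent <= 100:
        raise ValueError("k_percent must be in (0, 100]")
    if setting not in ("comprehensiveness", "sufficiency"):
        raise ValueError(f"unknown setting {setting!r}")
    T = sequence.layout.n_tokens
    if maskable is None:
        maskable = np.ones(T, dtype=bool)
    pool = ranking[maskable[ranking]]
    m = n_masked(k_percent, int(maskable.sum()))
    top = pool[:m]
    scale = np.ones(T, dtype=np.float32)
    if setting == "comprehensiveness":
        scale[top] = 0.0
    else:
        scale[maskable] = 0.0
        scale[top] = 1.0
    out = sequence.copy()
    out.tokens[scale == 0] = 0.0
    return out, scale


ExplainerFn = "callable[[TransformerRegressor, TokenSequence, str], ImportanceScores]"


def evaluate_faithfulness(
    model: TransformerRegressor,
    explainer,
    X: np.ndarray,
    levels: PerturbationLevels = PerturbationLevels(),
    method_name: str | None = None,
    maskable: np.ndarray | None = None,
) -> FaithfulnessReport:
    """Comprehensiveness/sufficiency deltas and AOPCR for one explainer.

    ``explainer(model, sequence, sample_id)`` must return ImportanceScores.
    Rankings are computed once per sample on the unperturbed input and
    reused across every level and both settings.  ``maskable`` restricts
    the perturbations to a token subset (see :func:`perturb`).
    """
    n = len(X)
    if n == 0:
        raise ValueError("empty sample set")
    T = model.layout.n_tokens
    if maskable is None:
        maskable = np.ones(T, dtype=bool)
    n_pool = int(maskable.sum())
    base = model.predict(X)
    rankings = np.empty((n, n_pool), dtype=int)
    name = method_name
    for i in range(n):
        sc = explainer(model, TokenSequence(np.asarray(X[i], float), model.layout),
                       str(i))
        if sc.T != T:
            raise ValueError("explainer returned scores of wrong length")
        r = rank_tokens(sc)
        rankings[i] = r[maskable[r]]
        name = name or sc.method

    per_level = {s: {"mae": [], "mse": []}
                 for s in ("comprehensiveness", "sufficiency")}
    for k in levels.levels:
        m = n_masked(k, n_pool)
        for setting in ("comprehensiveness", "sufficiency"):
            scale = np.ones((n, T), dtype=np.float32)
            if setting == "comprehensiveness":
                for i in range(n):
                    scale[i, rankings[i, :m]] = 0.0
            else:
                scale[:, maskable] = 0.0
                for i in range(n):
                    scale[i, rankings[i, :m]] = 1.0
            pert = model.predict(X, token_scale=scale)
            d = base - pert
            per_level[setting]["mae"].append(float(np.mean(np.abs(d))))
            per_level[setting]["mse"].append(float(np.mean(d ** 2)))

    aopcr = {f"{setting}_{metric}": float(np.mean(per_level[setting][metric]))
             for setting in per_level for metric in ("mae", "mse")}
    return FaithfulnessReport(method=name or "unnamed", n_samples=n,
                              levels=levels.levels, per_level=per_level,
                              aopcr=aopcr)


def compare_methods(
    model: TransformerRegressor,
    explainers: dict,
    X: np.ndarray,
    levels: PerturbationLevels = PerturbationLevels(),
    maskable: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, FaithfulnessReport]]:
    """Run several explainers on identical samples and rank them.

    ``explainers`` maps method name -> explainer callable.  A method whose
    explainer raises is recorded as failed and skipped; the run continues.
    Returns a summary table (one row per method, AOPCR columns, flags for
    best comprehensiveness and best sufficiency) plus the full reports.
    """
    if len(explainers) < 2:
        raise ValueError("need at least two methods to compare")
    reports: dict[str, FaithfulnessReport] = {}
    rows = []
    for name, fn in explainers.items():
        try:
            rep = evaluate_faithfulness(model, fn, X, levels, method_name=name,
                                        maskable=maskable)
        except Exception as exc:  # noqa: BLE001 - adapter failures reported
            rows.append({"method": name, "failed": True, "error": str(exc)})
            continue
        reports[name] = rep
        rows.append({"method": name, "failed": False, "error": "",
                     **rep.aopcr})
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    table["best_comprehensiveness"] = False
    table["best_sufficiency"] = False
    if not ok.empty:
        table.loc[ok["comprehensiveness_mae"].idxmax(),
                  "best_comprehensiveness"] = True
        table.loc[ok["sufficiency_mae"].idxmin(), "best_sufficiency"] = True
    return table, reports
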