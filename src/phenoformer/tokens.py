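"""Tokenization of daily weather plus context variables.

A growing season is split into consecutive multi-day windows; each
(variable, window) pair becomes one token whose d = 3 channels carry the
window maximum, minimum and mean.  Three context tokens follow the weather
run: location (standardized latitude/longitude), genotype cluster and
maturity group (categorical codes resolved to learned embeddings inside the
model).  Sequence layout, for V variables and P timepoints::

    [var0_win0 ... var0_win(P-1), var1_win0, ..., var(V-1)_win(P-1),
     loc, geno, mg]                         -> T = V * P + 3 tokens

Category token channel 0 stores an embedding-table index: 0 is the reserved
mask/pad code (whose embedding row is pinned to zero so that a zeroed token
is a true neutral input), 1 the reserved "unseen at inference" code, and
observed categories map to code + 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import DailyWeatherSeries, N_WEATHER_VARIABLES, WEATHER_VARIABLES

TOKEN_DIM = 3  # (max, min, mean) channels per token
MASK_CODE = 0
UNSEEN_CODE = 1
CODE_OFFSET = 2  # observed category c -> embedding index c + 2

#: Heavy-tailed daily variables are log1p-transformed before window
#: aggregation so that standardized tokens are not dominated by outliers.
LOG_TRANSFORM_VARS = ("prec",)


def downsample_weather(series: DailyWeatherSeries, interval_days: int,
                       log_vars: tuple[str, ...] = ()) -> np.ndarray:
    """Aggregate a 6 x n_days series into per-window (max, min, mean) tokens.

    Returns an array of shape (6, n_timepoints, 3) where
    n_timepoints = ceil(n_days / interval_days); the final window may be
    shorter and aggregates only its real days.  Variables named in
    ``log_vars`` are log1p-transformed daily before aggregation.
    """
    if interval_days < 1:
        raise ValueError("interval_days must be >= 1")
    v = series.values
    if log_vars:
        v = v.copy()
        for name in log_vars:
            i = WEATHER_VARIABLES.index(name)
            v[i] = np.log1p(np.maximum(v[i], 0.0))
    n_days = v.shape[1]
    n_tp = -(-n_days // interval_days)  # ceil
    out = np.empty((N_WEATHER_VARIABLES, n_tp, TOKEN_DIM))
    for w in range(n_tp):
        chunk = v[:, w * interval_days:min((w + 1) * interval_days, n_days)]
        out[:, w, 0] = chunk.max(axis=1)
        out[:, w, 1] = chunk.min(axis=1)
        out[:, w, 2] = chunk.mean(axis=1)
    return out


@dataclass
class TokenLayout:
    """Static description of the token sequence; shared by a whole dataset."""

    n_timepoints: int
    interval_days: int
    n_variables: int = N_WEATHER_VARIABLES
    variable_names: tuple[str, ...] = WEATHER_VARIABLES

    @property
    def n_weather_tokens(self) -> int:
        return self.n_variables * self.n_timepoints

    @property
    def n_tokens(self) -> int:
        return self.n_weather_tokens + 3

    @property
    def loc_index(self) -> int:
        return self.n_weather_tokens

    @property
    def geno_index(self) -> int:
        return self.n_weather_tokens + 1

    @property
    def mg_index(self) -> int:
        return self.n_weather_tokens + 2

    @property
    def category_indices(self) -> tuple[int, int]:
        return (self.geno_index, self.mg_index)

    def token_index(self, variable: int, timepoint: int) -> int:
        if not (0 <= variable < self.n_variables and 0 <= timepoint < self.n_timepoints):
            raise IndexError("variable/timepoint out of range")
        return variable * self.n_timepoints + timepoint

    def weather_mask(self) -> np.ndarray:
        m = np.zeros(self.n_tokens, dtype=bool)
        m[: self.n_weather_tokens] = True
        return m

    def variable_of(self, token: int) -> int | None:
        """Weather variable index of a token, or None for context tokens."""
        return token // self.n_timepoints if token < self.n_weather_tokens else None

    def meta_frame(self) -> pd.DataFrame:
        """Per-token metadata: kind, variable name, timepoint."""
        rows = []
        for t in range(self.n_weather_tokens):
            v, w = divmod(t, self.n_timepoints)
            rows.append({"token": t, "kind": "weather",
                         "variable": self.variable_names[v], "timepoint": w})
        for t, kind in ((self.loc_index, "location"), (self.geno_index, "genotype"),
                        (self.mg_index, "maturity")):
            rows.append({"token": t, "kind": kind, "variable": kind, "timepoint": -1})
        return pd.DataFrame(rows)


@dataclass
class NormalizationStats:
    """Train-split z-scoring statistics for weather channels, location and
    the regression target.  Degenerate channels fall back to sd = 1."""

    weather_mean: np.ndarray  # (6, 3)
    weather_sd: np.ndarray    # (6, 3)
    loc_mean: np.ndarray      # (2,)
    loc_sd: np.ndarray        # (2,)
    trait_mean: dict[str, float] = field(default_factory=dict)
    trait_sd: dict[str, float] = field(default_factory=dict)

    @staticmethod
    def fit(weather_tokens: np.ndarray, latlon: np.ndarray) -> "NormalizationStats":
        """``weather_tokens``: (n, 6, P, 3) train-split token values;
        ``latlon``: (n, 2)."""
        wm = weather_tokens.mean(axis=(0, 2))
        ws = weather_tokens.std(axis=(0, 2))
        ws[ws < 1e-8] = 1.0  # degenerate channel -> leave at 0 after centering
        lm, ls = latlon.mean(axis=0), latlon.std(axis=0)
        ls[ls < 1e-8] = 1.0
        return NormalizationStats(weather_mean=wm, weather_sd=ws,
                                  loc_mean=lm, loc_sd=ls)

    def fit_trait(self, name: str, values: np.ndarray) -> None:
        sd = float(np.std(values))
        self.trait_mean[name] = float(np.mean(values))
        self.trait_sd[name] = sd if sd > 0 else 1.0

    def standardize_trait(self, name: str, y: np.ndarray) -> np.ndarray:
        return (y - self.trait_mean[name]) / self.trait_sd[name]

    def destandardize_trait(self, name: str, y: np.ndarray) -> np.ndarray:
        return y * self.trait_sd[name] + self.trait_mean[name]


@dataclass
class TokenSequence:
    """One sample's token matrix plus the shared layout."""

    tokens: np.ndarray  # (T, 3) float
    layout: TokenLayout

    def copy(self) -> "TokenSequence":
        return TokenSequence(tokens=self.tokens.copy(), layout=self.layout)


def build_sequence(
    weather_tokens: np.ndarray,
    latitude: float,
    longitude: float,
    cluster_code: int,
    maturity_group: int,
    stats: NormalizationStats,
    layout: TokenLayout,
) -> TokenSequence:
    """Assemble one standardized token sequence.

    ``weather_tokens``: (6, P, 3) raw values from :func:`downsample_weather`;
    ``cluster_code``/``maturity_group`` are raw category values (cluster id,
    MG 0-9), mapped here to embedding-table codes.  A negative cluster code
    marks a genotype unseen at inference and maps to the reserved code.
    """
    T = layout.n_tokens
    x = np.zeros((T, TOKEN_DIM), dtype=np.float64)
    std = (weather_tokens - stats.weather_mean[:, None, :]) / stats.weather_sd[:, None, :]
    x[: layout.n_weather_tokens] = std.reshape(layout.n_weather_tokens, TOKEN_DIM)
    x[layout.loc_index, 0] = (latitude - stats.loc_mean[0]) / stats.loc_sd[0]
    x[layout.loc_index, 1] = (longitude - stats.loc_mean[1]) / stats.loc_sd[1]
    geno_code = UNSEEN_CODE if cluster_code < 0 else cluster_code + CODE_OFFSET
    x[layout.geno_index, 0] = geno_code
    x[layout.mg_index, 0] = maturity_group + CODE_OFFSET
    return TokenSequence(tokens=x, layout=layout)


@dataclass
class TokenDataset:
    """A tokenized trial dataset ready for model fitting.

    ``X`` stacks every record's token matrix: shape (n, T, 3), float32.
    ``traits`` maps trait name -> raw (unstandardized) values with NaN for
    missing.  ``index`` carries record metadata aligned with ``X`` rows.
    """

    X: np.ndarray
    traits: dict[str, np.ndarray]
    index: pd.DataFrame
    layout: TokenLayout
    stats: NormalizationStats
    n_clusters: int

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def sequence(self, i: int) -> TokenSequence:
        return TokenSequence(tokens=np.asarray(self.X[i], dtype=np.float64),
                             layout=self.layout)

    def subset(self, idx: np.ndarray) -> "TokenDataset":
        return TokenDataset(X=self.X[idx],
                            traits={k: v[idx] for k, v in self.traits.items()},
                            index=self.index.iloc[idx].reset_index(drop=True),
                            layout=self.layout, stats=self.stats,
                            n_clusters=self.n_clusters)


def tokenize_dataset(
    records: pd.DataFrame,
    weather: list[DailyWeatherSeries],
    clusters: dict[str, int],
    interval_days: int,
    stats: NormalizationStats | None = None,
    fit_mask: np.ndarray | None = None,
) -> TokenDataset:
    """Tokenize every performance record against its environment's weather.

    ``clusters`` maps genotype_id -> cluster id; genotypes absent from the
    map get the reserved unseen code.  Normalization statistics are fitted
    on the rows selected by ``fit_mask`` (default: all rows) unless ``stats``
    is supplied, in which case they are reused (the inference path).
    """
    env_map = {s.environment_id: s for s in weather}
    missing_envs = set(records["environment_id"]) - set(env_map)
    if missing_envs:
        raise ValueError(f"records reference unknown environments: {sorted(missing_envs)[:5]}")
    tok_cache = {eid: downsample_weather(s, interval_days,
                                         log_vars=LOG_TRANSFORM_VARS)
                 for eid, s in env_map.items()}
    n_tp = next(iter(tok_cache.values())).shape[1]
    layout = TokenLayout(n_timepoints=n_tp, interval_days=interval_days)

    wt = np.stack([tok_cache[e] for e in records["environment_id"]])
    latlon = records[["latitude", "longitude"]].to_numpy(dtype=float)
    if stats is None:
        sel = slice(None) if fit_mask is None else fit_mask
        stats = NormalizationStats.fit(wt[sel], latlon[sel])

    n = len(records)
    X = np.zeros((n, layout.n_tokens, TOKEN_DIM), dtype=np.float32)
    std = (wt - stats.weather_mean[None, :, None, :]) / stats.weather_sd[None, :, None, :]
    X[:, : layout.n_weather_tokens] = std.reshape(n, layout.n_weather_tokens, TOKEN_DIM)
    X[:, layout.loc_index, 0] = (latlon[:, 0] - stats.loc_mean[0]) / stats.loc_sd[0]
    X[:, layout.loc_index, 1] = (latlon[:, 1] - stats.loc_mean[1]) / stats.loc_sd[1]
    codes = np.array([clusters.get(g, -1) for g in records["genotype_id"]])
    X[:, layout.geno_index, 0] = np.where(codes < 0, UNSEEN_CODE, codes + CODE_OFFSET)
    X[:, layout.mg_index, 0] = records["maturity_group"].to_numpy() + CODE_OFFSET

    traits = {t: records[t].to_numpy(dtype=float) for t in ("yield", "oil", "protein")
              if t in records.columns}
    n_clusters = (max(clusters.values()) + 1) if clusters else 1
    return TokenDataset(X=X, traits=traits, index=records.reset_index(drop=True),
                        layout=layout, stats=stats, n_clusters=n_clusters)
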