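"""Synthetic multi-environment trial data with planted ground truth.

Emulates the three inputs a cooperative soybean trial network provides:
daily weather per environment, a pedigree connecting the tested genotypes,
and genotype-environment performance records (yield always observed; seed
oil and protein missing for whole environments at a time).  The trait model
plants known causal weather windows so downstream interpretability claims
have a verifiable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed order of the six daily weather variables used everywhere downstream.
WEATHER_VARIABLES = ("tmax", "tmin", "tavg", "hum", "prec", "rad")

N_WEATHER_VARIABLES = len(WEATHER_VARIABLES)

#: Units, for documentation and CSV headers.
WEATHER_UNITS = {
    "tmax": "degC", "tmin": "degC", "tavg": "degC",
    "hum": "%", "prec": "mm/day", "rad": "MJ/m2",
}

DEFAULT_SEASON_DAYS = 214


@dataclass
class DailyWeatherSeries:
    """One environment's daily weather for a growing season.

    ``values`` has shape (6, n_days) with rows ordered as
    :data:`WEATHER_VARIABLES`.  Invariants: tmin <= tavg <= tmax daily,
    humidity in [0, 100], precipitation and irradiance nonnegative.
    """

    environment_id: str
    year: int
    latitude: float
    longitude: float
    values: np.ndarray

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        v = self.values
        if v.shape[0] != N_WEATHER_VARIABLES or v.shape[1] < 1:
            raise ValueError(f"weather matrix must be 6 x n_days, got {v.shape}")
        tmax, tmin, tavg = v[0], v[1], v[2]
        if not (np.all(tmin <= tavg + 1e-9) and np.all(tavg <= tmax + 1e-9)):
            raise ValueError("temperature ordering tmin <= tavg <= tmax violated")
        if np.any(v[3] < 0) or np.any(v[3] > 100):
            raise ValueError("humidity outside [0, 100]")
        if np.any(v[4] < 0) or np.any(v[5] < 0):
            raise ValueError("precipitation/irradiance must be nonnegative")


@dataclass
class TruthMap:
    """Planted generative truth for the trait model.

    ``causal_windows`` is a list of ``(variable_index, start_day, end_day,
    weight)`` tuples; the response adds ``weight * mean(values[var, start:end])``
    for each window.  Oil and protein reuse the same window means (the shared
    latent weather signals) with their own coefficient vectors, so that a
    yield-pretrained encoder genuinely transfers.
    """

    causal_windows: list[tuple[int, int, int, float]]
    genotype_effect_sd: float = 3.0
    noise_sd: float = 3.0
    #: genotype-by-environment interaction: families modulate the first
    #: causal window's weight by (1 + gxe_scale * u_family), u ~ N(0,1).
    #: 0 recovers a purely additive response.
    gxe_scale: float = 0.0
    trait_coefficients: dict[str, np.ndarray] = field(default_factory=dict)
    trait_intercepts: dict[str, float] = field(
        default_factory=lambda: {"yield": 45.0, "oil": 20.0, "protein": 35.0})
    #: per-trait multiplier on the genotype effect (and its G x E term);
    #: seed-composition traits carry weaker genetic main effects than yield.
    trait_geno_scale: dict[str, float] = field(
        default_factory=lambda: {"yield": 1.0, "oil": 0.6, "protein": 0.8})
    mg_effects: np.ndarray = field(
        default_factory=lambda: 2.5 * ((np.arange(10) - 4.5) / 4.5) ** 2 - 1.0)

    def validate(self, n_days: int) -> None:
        for var, start, end, weight in self.causal_windows:
            if not (0 <= var < N_WEATHER_VARIABLES):
                raise ValueError(f"variable index {var} out of range")
            if not (0 <= start < end <= n_days):
                raise ValueError(f"window [{start}, {end}) outside [0, {n_days})")
            if not np.isfinite(weight):
                raise ValueError("window weight must be finite")
        if self.noise_sd < 0 or self.genotype_effect_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


def _seasonal(day: np.ndarray, n_days: int, peak: float, amplitude: float) -> np.ndarray:
    # Half-sine over the season: cool shoulders, warm mid-season.
    return peak - amplitude + amplitude * np.sin(np.pi * (day + 0.5) / n_days)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size=n)
    out = np.empty(n)
    x = rng.normal(0.0, sd)
    for t in range(n):
        x = phi * x + innov[t]
        out[t] = x
    return out


def generate_weather(
    n_environments: int,
    n_days: int = DEFAULT_SEASON_DAYS,
    seed: int = 0,
    year: int = 2000,
    noise_scale: float = 1.0,
    lat_range: tuple[float, float] = (30.0, 48.0),
) -> list[DailyWeatherSeries]:
    """Simulate daily weather for ``n_environments`` growing seasons.

    Each variable is a seasonal half-sine plus AR(1) deviations (phi = 0.7);
    the seasonal mean temperature and irradiance shift with latitude so that
    environments are genuinely distinct.  Mean temperature is simulated and
    max/min derived as mean +/- positive half-ranges, which guarantees the
    ordering invariant by construction.  Deterministic given ``seed``.

    ``noise_scale`` scales the thermal and radiative AR(1) variability
    (temperatures, irradiance); humidity and precipitation keep unit scale —
    inflating a rectified variable like precipitation only adds
    zero-inflation artifacts, not usable signal.
    """
    if n_environments < 1 or n_days < 1:
        raise ValueError("n_environments and n_days must be positive")
    rng = np.random.default_rng(seed)
    day = np.arange(n_days, dtype=float)
    out: list[DailyWeatherSeries] = []
    for e in range(n_environments):
        lat = rng.uniform(*lat_range)
        lon = rng.uniform(-104.0, -76.0)
        warm = 27.0 - 0.35 * (lat - 30.0)  # cooler mean season at high latitude
        tavg = _seasonal(day, n_days, peak=warm, amplitude=7.0)
        tavg = tavg + _ar1(rng, n_days, 0.7, 2.2 * noise_scale)
        hi = 4.5 + np.abs(_ar1(rng, n_days, 0.5, 1.2 * noise_scale))
        lo = 5.5 + np.abs(_ar1(rng, n_days, 0.5, 1.2 * noise_scale))
        tmax, tmin = tavg + hi, tavg - lo
        hum = np.clip(72.0 + _ar1(rng, n_days, 0.7, 8.0), 0.0, 100.0)
        prec = np.maximum(0.0, 2.5 + _ar1(rng, n_days, 0.4, 3.5))
        rad_peak = 26.0 - 0.15 * (lat - 30.0)
        rad = np.maximum(
            0.0, _seasonal(day, n_days, peak=rad_peak, amplitude=9.0)
            + _ar1(rng, n_days, 0.6, 2.5 * noise_scale))
        series = DailyWeatherSeries(
            environment_id=f"E{e:04d}", year=year, latitude=float(lat),
            longitude=float(lon),
            values=np.vstack([tmax, tmin, tavg, hum, prec, rad]))
        series.validate()
        out.append(series)
    return out


def generate_pedigree(
    n_founders: int,
    n_generations: int,
    seed: int = 0,
    n_families: int = 2,
    offspring_per_pair: int = 2,
) -> pd.DataFrame:
    """Simulate a breeding pedigree with separable kinship families.

    Founders are split into ``n_families`` isolated groups; matings only
    occur within a group, so the additive relationship matrix is
    block-diagonal across families.  Columns: ``individual``, ``sire``,
    ``dam`` (empty string = unknown parent), plus bookkeeping columns
    ``generation`` and ``family``.  The table is topologically sorted:
    parents always precede offspring.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_generations < 0:
        raise ValueError("n_generations must be nonnegative")
    n_families = max(1, min(n_families, n_founders // 2))
    rng = np.random.default_rng(seed)
    rows = []
    current: dict[int, list[str]] = {f: [] for f in range(n_families)}
    for i in range(n_founders):
        fam = i % n_families
        ind = f"G{len(rows):05d}"
        rows.append({"individual": ind, "sire": "", "dam": "",
                     "generation": 0, "family": fam})
        current[fam].append(ind)
    for g in range(1, n_generations + 1):
        nxt: dict[int, list[str]] = {f: [] for f in range(n_families)}
        for fam, parents in current.items():
            if len(parents) < 2:
                nxt[fam] = parents
                continue
            perm = rng.permutation(len(parents))
            for k in range(0, len(perm) - 1, 2):
                sire, dam = parents[perm[k]], parents[perm[k + 1]]
                for _ in range(offspring_per_pair):
                    ind = f"G{len(rows):05d}"
                    rows.append({"individual": ind, "sire": sire, "dam": dam,
                                 "generation": g, "family": fam})
                    nxt[fam].append(ind)
        current = nxt
    return pd.DataFrame(rows)


def _window_means(series: DailyWeatherSeries, truth: TruthMap) -> np.ndarray:
    """The latent weather signals: one mean per causal window."""
    return np.array([series.values[var, start:end].mean()
                     for var, start, end, _ in truth.causal_windows])


def environment_signal(series: DailyWeatherSeries, truth: TruthMap) -> float:
    """Yield-scale weather contribution of one environment (no noise)."""
    means = _window_means(series, truth)
    weights = np.array([w for *_, w in truth.causal_windows])
    return float(means @ weights)


def generate_trials(
    weather: list[DailyWeatherSeries],
    pedigree: pd.DataFrame,
    truth: TruthMap,
    n_genotypes_per_env: int = 20,
    missing_oil_protein_fraction: float = 0.493,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate performance records over environments x genotypes.

    Trait model per record::

        trait = intercept + sum_w coeff[w] * window_mean[w]
                + genotype family effect + maturity-group effect + noise

    The genotype effect is drawn once per pedigree family (scaled by
    ``truth.genotype_effect_sd``), making it recoverable from a kinship
    cluster token.  Oil/protein missingness is environment-blocked:
    environments are masked whole, sampled without replacement until the
    realized missing record fraction first reaches the requested one
    (within 2 percentage points when environments are reasonably many).
    """
    if not weather:
        raise ValueError("weather collection is empty")
    if pedigree.empty:
        raise ValueError("pedigree is empty")
    if not 0.0 <= missing_oil_protein_fraction <= 1.0:
        raise ValueError("missing fraction must be in [0, 1]")
    n_days = weather[0].n_days
    truth.validate(n_days)
    rng = np.random.default_rng(seed)

    genos = pedigree["individual"].to_numpy()
    if "family" in pedigree.columns:
        families = pedigree["family"].to_numpy()
    else:
        families = np.zeros(len(genos), dtype=int)
    fam_ids = np.unique(families)
    fam_effect = {f: rng.normal(0.0, truth.genotype_effect_sd) for f in fam_ids}
    fam_sens = {f: float(np.clip(rng.normal(0.0, 1.0), -2.0, 2.0)) for f in fam_ids}
    geno_family = dict(zip(genos, families))
    # centered first-window signal for the G x E interaction term
    if truth.gxe_scale != 0.0 and truth.causal_windows:
        w0 = np.array([_window_means(s, truth)[0] for s in weather])
        w0_mean, w0_sd = float(w0.mean()), float(w0.std()) or 1.0
    # Maturity group tracks latitude adaptation with a little spread.
    lat = np.array([s.latitude for s in weather])
    env_mg = np.clip(np.round((48.0 - lat) / 2.0
                              + rng.normal(0, 0.7, len(weather))), 0, 9).astype(int)

    weights = np.array([w for *_, w in truth.causal_windows])
    coeffs = {"yield": weights}
    for trait in ("oil", "protein"):
        c = truth.trait_coefficients.get(trait)
        coeffs[trait] = weights if c is None else np.asarray(c, dtype=float)
    trait_geno_scale = truth.trait_geno_scale

    rows = []
    for i, series in enumerate(weather):
        signals = _window_means(series, truth)
        chosen = rng.choice(len(genos), size=min(n_genotypes_per_env, len(genos)),
                            replace=False)
        for j in chosen:
            g = genos[j]
            mg = int(np.clip(env_mg[i] + rng.integers(-1, 2), 0, 9))
            rec = {"genotype_id": g, "environment_id": series.environment_id,
                   "year": series.year, "latitude": series.latitude,
                   "longitude": series.longitude, "maturity_group": mg,
                   "family": int(geno_family[g])}
            fam = geno_family[g]
            if truth.gxe_scale != 0.0 and truth.causal_windows:
                # family-specific sensitivity to the first causal window,
                # on the same scale as that window's main effect
                w0_anom = (signals[0] - w0_mean) / w0_sd
                gxe = (truth.gxe_scale * fam_sens[fam]
                       * abs(truth.causal_windows[0][3]) * w0_sd * w0_anom)
            else:
                gxe = 0.0
            for trait in ("yield", "oil", "protein"):
                val = (truth.trait_intercepts[trait]
                       + float(coeffs[trait] @ signals)
                       + trait_geno_scale[trait] * fam_effect[fam]
                       + trait_geno_scale[trait] * gxe
                       + float(truth.mg_effects[mg])
                       + rng.normal(0.0, truth.noise_sd))
                rec[trait] = val
            rows.append(rec)
    records = pd.DataFrame(rows)

    # Environment-blocked oil/protein missingness.
    env_order = rng.permutation(records["environment_id"].unique())
    env_counts = records["environment_id"].value_counts()
    total = len(records)
    masked_envs: list[str] = []
    missing = 0
    for env in env_order:
        if missing / total >= missing_oil_protein_fraction:
            break
        masked_envs.append(env)
        missing += int(env_counts[env])
    records.loc[records["environment_id"].isin(masked_envs),
                ["oil", "protein"]] = np.nan
    return records


def default_truth(n_days: int = DEFAULT_SEASON_DAYS) -> TruthMap:
    """The standard benchmark truth: causality in mid-season radiation and
    max temperature, echoing the agronomic expectation that irradiance and
    heat during seed fill drive yield.

    Oil is deliberately the *hard, scarce* trait: it shares yield's latent
    radiation signal but with small coefficients and a weak genetic main
    effect, so its attainable accuracy from a few hundred labeled records
    is low — the regime where reusing a yield-pretrained encoder matters.
    Protein keeps a strong temperature loading and genetic effect.
    """
    rad, tmax = WEATHER_VARIABLES.index("rad"), WEATHER_VARIABLES.index("tmax")
    a, b = int(0.40 * n_days), int(0.60 * n_days)
    c, d = int(0.30 * n_days), int(0.50 * n_days)
    windows = [(rad, a, b, 1.2), (tmax, c, d, -0.9)]
    return TruthMap(
        causal_windows=windows,
        trait_coefficients={
            # oil: weak, radiation-loaded; protein: temperature-loaded
            "oil": np.array([0.385, -0.07]),
            "protein": np.array([0.3, -1.2]),
        },
        trait_geno_scale={"yield": 1.0, "oil": 0.15, "protein": 0.8},
    )


# ---------------------------------------------------------------------------
# CSV writers / readers

def write_weather_csv(weather: list[DailyWeatherSeries], path) -> None:
    """Long-format CSV: environment_id, year, latitude, longitude, day,
    tmax, tmin, tavg, hum, prec, rad."""
    frames = []
    for s in weather:
        df = pd.DataFrame(s.values.T, columns=list(WEATHER_VARIABLES))
        df.insert(0, "day", np.arange(s.n_days))
        df.insert(0, "longitude", s.longitude)
        df.insert(0, "latitude", s.latitude)
        df.insert(0, "year", s.year)
        df.insert(0, "environment_id", s.environment_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_weather_csv(path) -> list[DailyWeatherSeries]:
    df = pd.read_csv(path)
    out = []
    for env, grp in df.groupby("environment_id", sort=False):
        grp = grp.sort_values("day")
        out.append(DailyWeatherSeries(
            environment_id=str(env), year=int(grp["year"].iloc[0]),
            latitude=float(grp["latitude"].iloc[0]),
            longitude=float(grp["longitude"].iloc[0]),
            values=grp[list(WEATHER_VARIABLES)].to_numpy().T))
    return out


def write_pedigree_csv(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, index=False)


def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
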