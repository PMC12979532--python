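"""End-to-end experiment pipelines over synthetic trial scenarios.

A `Scenario` bundles every generator parameter with a seed, so any run is
reconstructible from its YAML dump.  `make_dataset` chains weather,
pedigree and trial generation, builds the kinship matrix, clusters
genotypes, and tokenizes the records with normalization statistics fitted
on the training split only.  On top of that sit the temporal-resolution
sweep and the feature-set ablation (genetics only / + weather /
+ management).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from . import synth
from .kinship import a_matrix, cluster_features, cluster_genotypes
from .metrics import MetricSet, metrics
from .model import ModelConfig, SplitSpec, TrainResult, train_model
from .synth import TruthMap, default_truth
from .tokens import MASK_CODE, TokenDataset, tokenize_dataset


@dataclass
class Scenario:
    """Synthetic study conditions.

    Defaults emulate a modest multi-environment trial network: 40
    environments x up to 40 tested genotypes from a 6-family pedigree, a
    214-day season tokenized at a 28-day interval, trait noise at a third
    of the planted signal spread, and environment-blocked oil/protein
    missingness at the observed 49.3% record rate.
    """

    n_environments: int = 40
    n_days: int = synth.DEFAULT_SEASON_DAYS
    n_founders: int = 24
    n_generations: int = 3
    n_families: int = 6
    n_genotypes_per_env: int = 40
    interval_days: int = 28
    noise_sd: float | None = None  # None -> derived from snr
    snr: float = 3.0
    genotype_effect_sd: float = 3.0
    gxe_scale: float = 0.0
    weather_noise_scale: float = 1.0
    lat_range: tuple[float, float] = (30.0, 48.0)
    missing_fraction: float = 0.493
    seed: int = 0

    def __post_init__(self):
        self.lat_range = tuple(self.lat_range)  # YAML round-trips as a list

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["lat_range"] = list(d["lat_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @staticmethod
    def from_yaml(path) -> "Scenario":
        with open(path) as fh:
            return Scenario(**yaml.safe_load(fh))


@dataclass
class BuiltData:
    scenario: Scenario
    truth: TruthMap
    weather: list
    pedigree: pd.DataFrame
    records: pd.DataFrame
    clusters: dict[str, int]
    cluster_k: int


def resolve_noise_sd(scenario: Scenario, truth: TruthMap,
                     weather, pedigree) -> float:
    """Noise level implied by the scenario's signal-to-noise ratio.

    SNR is defined as sd(noise-free response) / noise_sd over a noiseless
    draw of the records, so R² attainable by an ideal predictor is
    snr² / (snr² + 1).
    """
    if scenario.noise_sd is not None:
        return scenario.noise_sd
    quiet = replace(truth, noise_sd=0.0)
    rec = synth.generate_trials(weather, pedigree, quiet,
                                scenario.n_genotypes_per_env,
                                missing_oil_protein_fraction=0.0,
                                seed=scenario.seed + 2)
    signal_sd = float(rec["yield"].std())
    return signal_sd / scenario.snr


def build_data(scenario: Scenario, truth: TruthMap | None = None) -> BuiltData:
    """Generate one full synthetic study and cluster its genotypes."""
    if truth is None:
        truth = default_truth(scenario.n_days)
    truth = replace(truth, genotype_effect_sd=scenario.genotype_effect_sd,
                    gxe_scale=scenario.gxe_scale)
    weather = synth.generate_weather(scenario.n_environments, scenario.n_days,
                                     seed=scenario.seed,
                                     noise_scale=scenario.weather_noise_scale,
                                     lat_range=tuple(scenario.lat_range))
    pedigree = synth.generate_pedigree(scenario.n_founders,
                                       scenario.n_generations,
                                       seed=scenario.seed + 1,
                                       n_families=scenario.n_families)
    truth = replace(truth,
                    noise_sd=resolve_noise_sd(scenario, truth, weather, pedigree))
    records = synth.generate_trials(weather, pedigree, truth,
                                    scenario.n_genotypes_per_env,
                                    scenario.missing_fraction,
                                    seed=scenario.seed + 2)
    A = a_matrix(pedigree)
    feats = cluster_features(A, records)
    assign = cluster_genotypes(feats, k=scenario.n_families, seed=scenario.seed)
    return BuiltData(scenario=scenario, truth=truth, weather=weather,
                     pedigree=pedigree, records=records,
                     clusters=assign.as_mapping(), cluster_k=assign.k)


def make_dataset(data: BuiltData, interval_days: int | None = None,
                 split: SplitSpec | None = None
                 ) -> tuple[TokenDataset, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Tokenize the records; normalization statistics use the training rows.

    The returned split indexes rows of the full record table (the yield
    task; trait-specific subsetting happens inside training).
    """
    split = split or SplitSpec(seed=data.scenario.seed)
    iv = interval_days or data.scenario.interval_days
    tr, va, te = split.indices(len(data.records))
    fit_mask = np.zeros(len(data.records), dtype=bool)
    fit_mask[tr] = True
    ds = tokenize_dataset(data.records, data.weather, data.clusters, iv,
                          fit_mask=fit_mask)
    return ds, (tr, va, te)


@dataclass
class RunResult:
    train: TrainResult
    test_metrics: MetricSet
    dataset: TokenDataset
    split: tuple


def run_yield_model(data: BuiltData, config: ModelConfig,
                    interval_days: int | None = None,
                    split: SplitSpec | None = None) -> RunResult:
    """Tokenize, train on yield, and score the held-out test set."""
    ds, idx = make_dataset(data, interval_days, split)
    res = train_model(ds, "yield", config, idx)
    _tr, _va, te = idx
    pred = res.model.predict(ds.X[te])
    m = metrics(ds.traits["yield"][te], pred, trait="yield", seed=config.seed)
    return RunResult(train=res, test_metrics=m, dataset=ds, split=idx)


# ---------------------------------------------------------------------------
# Temporal-resolution sweep

def resolution_sweep(data: BuiltData, config: ModelConfig, intervals: list[int],
                     seeds: list[int]) -> pd.DataFrame:
    """Re-tokenize, retrain and evaluate at each sampling interval.

    Normalization statistics are re-fitted per interval (they depend on the
    tokenization).  Returns one row per (interval, seed) plus mean/sd
    aggregation columns merged in.
    """
    rows = []
    for iv in intervals:
        for seed in seeds:
            cfg = replace(config, seed=seed)
            run = run_yield_model(data, cfg, interval_days=iv,
                                  split=SplitSpec(seed=seed))
            rows.append({"interval_days": iv, "seed": seed,
                         "n_timepoints": run.dataset.layout.n_timepoints,
                         **{k: v for k, v in run.test_metrics.as_dict().items()
                            if k in ("r2", "rmse", "mae", "n")}})
    df = pd.DataFrame(rows)
    agg = df.groupby("interval_days")["r2"].agg(["mean", "std"]).rename(
        columns={"mean": "r2_mean", "std": "r2_sd"})
    return df.merge(agg, on="interval_days")


# ---------------------------------------------------------------------------
# Feature-set ablation

FEATURE_SETS = ("genetics_only", "genetics_weather", "genetics_weather_management")


def apply_feature_set(ds: TokenDataset, feature_set: str) -> TokenDataset:
    """Zero out the tokens excluded by a feature set.

    Genetics = the genotype-cluster token; weather = the full weather run;
    management = maturity group + location.  Zeroed continuous tokens and
    the mask category code are both true neutral inputs to the model.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    lay = ds.layout
    X = ds.X.copy()
    if feature_set == "genetics_only":
        X[:, : lay.n_weather_tokens] = 0.0
        X[:, lay.loc_index] = 0.0
        X[:, lay.mg_index] = MASK_CODE
    elif feature_set == "genetics_weather":
        X[:, lay.loc_index] = 0.0
        X[:, lay.mg_index] = MASK_CODE
    return TokenDataset(X=X, traits=ds.traits, index=ds.index, layout=lay,
                        stats=ds.stats, n_clusters=ds.n_clusters)


def ablation(data: BuiltData, config: ModelConfig,
             feature_sets=FEATURE_SETS, seeds: list[int] = (0,),
             trait: str = "yield") -> pd.DataFrame:
    """Mean test R² per feature set across seeds."""
    rows = []
    for seed in seeds:
        split = SplitSpec(seed=seed)
        ds, idx = make_dataset(data, split=split)
        for fs in feature_sets:
            sub = apply_feature_set(ds, fs)
            cfg = replace(config, seed=seed)
            res = train_model(sub, trait, cfg, idx)
            te = idx[2]
            pred = res.model.predict(sub.X[te])
            m = metrics(sub.traits[trait][te], pred, trait=trait, seed=seed)
            rows.append({"feature_set": fs, "seed": seed, "r2": m.r2,
                         "rmse": m.rmse, "mae": m.mae})
    df = pd.DataFrame(rows)
    agg = df.groupby("feature_set")["r2"].agg(["mean", "std"]).rename(
        columns={"mean": "r2_mean", "std": "r2_sd"})
    return df.merge(agg, on="feature_set")
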