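"""Shared fixtures: the synthetic benchmark study and trained models.

Training is the expensive step, so trained models are session-scoped and
shared across the interpretability, faithfulness, transfer and comparison
tests; every consumer treats them as read-only.
"""

from dataclasses import replace

import numpy as np
import pytest

from phenoformer.experiments import Scenario, build_data, run_yield_model
from phenoformer.model import ModelConfig, SplitSpec

#: The standard benchmark study: a regional trial network with planted
#: causality in mid-season solar irradiance and maximum temperature, a
#: genotype-by-environment interaction on the irradiance window, signal-to-
#: noise 3, and environment-blocked oil/protein missingness leaving ~500
#: labeled oil records (the data-scarce transfer condition).
BENCHMARK = Scenario(
    n_environments=50, n_genotypes_per_env=40, snr=3.0, interval_days=28,
    gxe_scale=1.0, weather_noise_scale=2.0, lat_range=(36.0, 44.0),
    missing_fraction=0.75, seed=0)

#: Desk-scale model used for the multi-seed benchmark experiments.
SMALL_MODEL = ModelConfig(d_model=32, n_layers=2, n_heads=4, d_ff=64,
                          dropout=0.1, lr=2e-3, batch_size=64,
                          max_epochs=40, patience=20, seed=0)


@pytest.fixture(scope="session")
def bench_data():
    return build_data(BENCHMARK)


@pytest.fixture(scope="session")
def bench_run(bench_data):
    """The reference yield model on the 28-day benchmark tokenization."""
    return run_yield_model(bench_data, replace(SMALL_MODEL, seed=0))


@pytest.fixture(scope="session")
def bench_runs_14(bench_data):
    """Five seeded yield models at the 14-day tokenization (attention
    recovery operates at the finer interpretability resolution)."""
    return [run_yield_model(bench_data,
                            replace(SMALL_MODEL, seed=s, max_epochs=30,
                                    patience=15),
                            interval_days=14, split=SplitSpec(seed=s))
            for s in range(5)]


@pytest.fixture(scope="session")
def tiny_run():
    """A fast, small study for mechanics tests (shapes, round-trips,
    attribution axioms); one 2-layer model on ~600 records."""
    sc = Scenario(n_environments=20, n_days=112, n_genotypes_per_env=30,
                  snr=4.0, interval_days=28, weather_noise_scale=2.0,
                  n_founders=12, n_families=4, missing_fraction=0.3, seed=7)
    data = build_data(sc)
    cfg = ModelConfig(d_model=16, n_layers=2, n_heads=2, d_ff=32, dropout=0.1,
                      lr=2e-3, batch_size=64, max_epochs=15, patience=10, seed=7)
    return data, run_yield_model(data, cfg, split=SplitSpec(seed=7))
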