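#!/usr/bin/env python
"""Fit LASSO, SVR-RBF, BRNN and BLSTM on the benchmark study and tabulate
test metrics against the transformer, all on identical splits."""

import argparse
from dataclasses import replace
from pathlib import Path

import pandas as pd

from phenoformer.baselines import (BASELINE_KINDS, BaselineSpec, fit_baseline,
                                   flat_features, sequence_features)
from phenoformer.experiments import build_data, run_yield_model
from phenoformer.metrics import metrics
from phenoformer.model import ModelConfig, SplitSpec

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "simulate", Path(__file__).with_name("01_simulate_trials.py"))
_sim = _ilu.module_from_spec(_spec); _spec.loader.exec_module(_sim)

ROOT = Path(__file__).resolve().parents[1]

TRANSFORMER = ModelConfig(d_model=32, n_layers=2, n_heads=4, d_ff=64,
                          dropout=0.1, lr=2e-3, batch_size=64, max_epochs=40,
                          patience=20)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, nargs="+", default=[0, 1, 2])
    ap.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    data = build_data(_sim.benchmark_scenario(args.seeds[0]))
    rows = []
    for seed in args.seeds:
        run = run_yield_model(data, replace(TRANSFORMER, seed=seed),
                              split=SplitSpec(seed=seed))
        ds, te = run.dataset, run.split[2]
        y = ds.traits["yield"][te]
        m = run.test_metrics
        rows.append({"model": "transformer", "seed": seed, "r2": m.r2,
                     "rmse": m.rmse, "mae": m.mae})
        for kind in BASELINE_KINDS:
            fit = fit_baseline(BaselineSpec(kind=kind, seed=seed), ds,
                               "yield", run.split)
            feats = (sequence_features(ds) if kind in ("brnn", "blstm")
                     else flat_features(ds))
            mb = metrics(y, fit.predict(feats[te]))
            rows.append({"model": kind, "seed": seed, "r2": mb.r2,
                         "rmse": mb.rmse, "mae": mb.mae,
                         "hyperparams": str(fit.chosen)})
    table = pd.DataFrame(rows)
    summary = table.groupby("model")[["r2", "rmse", "mae"]].agg(["mean", "std"])
    args.outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.outdir / "baseline_runs.csv", index=False)
    summary.to_csv(args.outdir / "baseline_summary.csv")
    print(summary.round(3).to_string())


if __name__ == "__main__":
    main()
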