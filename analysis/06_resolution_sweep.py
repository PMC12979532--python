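#!/usr/bin/env python
"""Sweep the weather sampling interval (days per token) and chart test R²
per temporal resolution, mean +/- sd over seeds."""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from phenoformer.experiments import build_data, resolution_sweep
from phenoformer.model import ModelConfig

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "simulate", Path(__file__).with_name("01_simulate_trials.py"))
_sim = _ilu.module_from_spec(_spec); _spec.loader.exec_module(_sim)

ROOT = Path(__file__).resolve().parents[1]

CONFIG = ModelConfig(d_model=32, n_layers=2, n_heads=4, d_ff=64, dropout=0.1,
                     lr=2e-3, batch_size=64, max_epochs=30, patience=15)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--intervals", type=int, nargs="+",
                    default=[7, 14, 28, 54])
    ap.add_argument("--seeds", type=int, nargs="+", default=[0, 1, 2])
    ap.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    data = build_data(_sim.benchmark_scenario(args.seeds[0]))
    table = resolution_sweep(data, CONFIG, args.intervals, args.seeds)
    args.outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.outdir / "resolution_sweep.csv", index=False)

    agg = table.drop_duplicates("interval_days")[
        ["interval_days", "r2_mean", "r2_sd"]]
    print(agg.to_string(index=False))
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.errorbar(agg["interval_days"], agg["r2_mean"], yerr=agg["r2_sd"],
                marker="o")
    ax.set_xlabel("days per token")
    ax.set_ylabel("test R²")
    ax.set_title("Temporal resolution vs prediction accuracy")
    fig.tight_layout()
    fig.savefig(args.outdir / "resolution_sweep.png", dpi=150)
    print(f"figure: {args.outdir / 'resolution_sweep.png'}")


if __name__ == "__main__":
    main()
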