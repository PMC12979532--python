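# phenoformer

Transformer-based prediction of soybean trait performance — seed yield,
oil and protein — across multi-environment breeding trials, from daily
weather, pedigree-derived genotype clusters, maturity group and location;
with transfer learning for data-scarce traits, attention- and
gradient-based interpretability, and quantitative faithfulness evaluation
of the explanations.

It is written for quantitative geneticists and agricultural ML
practitioners who want a tested, end-to-end reference implementation of
this modelling pattern that runs on a laptop. Because large cooperative
trial datasets are not freely redistributable, the package includes a
synthetic trial generator with *planted* causal structure (known weather
windows, family effects, genotype-by-environment interaction,
environment-blocked trait missingness), so every stage has a verifiable
recovery target.

## The model

Each record's growing season is tokenized: the daily series of six
weather variables (max/min/mean air temperature, relative humidity,
precipitation, solar irradiance) is split into multi-day windows, one
token per (variable, window) carrying that window's max/min/mean; three
context tokens (location, genotype cluster, maturity group) are appended,
giving T = 6P + 3 tokens. Tokens are embedded and positionally encoded,

    z_i = E x_i + p_i

passed through N stacked encoder blocks (multi-head self-attention +
feedforward), and the flattened final representations feed a linear
regression head

    ŷ = W_reg · concat(z^(N)) + b_reg

trained with MSE loss, Adam, cosine learning-rate decay and early
stopping. Genotype relatedness enters through the pedigree-based additive
relationship matrix (tabular method), clustered by K-means together with
mean location yield; the cluster id is the genotype token. For oil and
protein — missing for whole environments at a time in real networks — a
yield-pretrained encoder is reused either frozen (new head only) or
fine-tuned end to end, against a from-scratch "vanilla" control.

Interpretability: per-token importance from mean received attention
(aggregated over heads and layers) and from integrated gradients,
GradientSHAP and LIME; faithfulness of every method is quantified by
masking top-k tokens (k ∈ {5, 7.5, 10, 15, 25}%) and aggregating
prediction deltas into comprehensiveness and sufficiency AOPCR.

The neural stack (transformer, bidirectional RNN/LSTM baselines,
backprop, Adam) is implemented directly in NumPy; gradient correctness is
pinned by finite-difference tests. LASSO/SVR baselines and K-means come
from scikit-learn.

## Worked example

```python
from dataclasses import replace
from phenoformer.experiments import Scenario, build_data, run_yield_model
from phenoformer.model import ModelConfig

scenario = Scenario(n_environments=50, n_genotypes_per_env=40, snr=3.0,
                    interval_days=28, gxe_scale=1.0, weather_noise_scale=2.0,
                    lat_range=(36.0, 44.0), missing_fraction=0.75, seed=0)
data = build_data(scenario)          # weather, pedigree, records, clusters
run = run_yield_model(data, ModelConfig(d_model=32, n_layers=2, n_heads=4,
                                        d_ff=64, lr=2e-3, batch_size=64,
                                        max_epochs=40, seed=0))
print(run.test_metrics)
```

prints (seed 0, one CPU):

    MetricSet(r2=0.8953546522801907, rmse=1.744235237335829,
              mae=1.409206357081552, n=200, trait='yield', seed=0)

i.e. the model explains 89.5% of held-out yield variance on a scenario
whose noise ceiling is R² = 0.9 (signal-to-noise 3): it has recovered
nearly all of the planted weather, genetic and G×E signal. The numbered
scripts under `analysis/` continue from here — clustering diagnostics,
baseline comparison, oil/protein transfer, the temporal-resolution sweep,
attention profiles over the season, the faithfulness table and the
feature-set ablation — each writing its tables under `results/`.

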