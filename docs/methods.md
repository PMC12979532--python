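# Methods

`phenoformer` implements a transformer-based pipeline for predicting
soybean trait performance (seed yield, oil, protein) across
multi-environment trials from daily weather, pedigree-derived genotype
clusters, maturity group and location, together with the interpretability
and faithfulness machinery needed to ask *which* inputs the model uses.
Because the historical trial data this kind of study draws on is not
freely redistributable, the package ships a synthetic-data generator that
emulates the study conditions with known, planted ground truth; every
claim the test suite makes is a recovery claim against that truth.

## Synthetic trial generator

**Weather.** Each environment's season (default 214 days) is simulated per
variable as a seasonal half-sine plus AR(1) deviations (daily
autocorrelation 0.7). Mean air temperature is simulated directly and
max/min derived as mean ± positive half-ranges, which guarantees
`tmin ≤ tavg ≤ tmax` by construction. Seasonal temperature and irradiance
levels decline with latitude, so environments are spatially structured.
Humidity is clipped to [0, 100]; precipitation is a rectified AR(1) (zero
on dry days); irradiance is nonnegative. The `noise_scale` parameter
scales thermal/radiative AR variability only — inflating a rectified
variable like precipitation adds zero-inflation artifacts rather than
usable signal.

**Pedigree.** Founders are split into isolated families; matings occur
only within a family, each generation pairing the previous one's
individuals. The additive relationship matrix is therefore block-diagonal
across families, giving clustering a recoverable target.

**Traits.** For each record (genotype × environment),

    trait = intercept + Σ_w β_w · mean(variable_w over window_w)
            + family effect + maturity-group effect + ε,   ε ~ N(0, σ²)

The causal windows (variable, day span, weight) are the planted ground
truth. Oil and protein reuse the same window means with their own
coefficient vectors (oil loads on the irradiance window, protein on the
temperature window), so a yield-pretrained encoder genuinely carries
transferable signal. In the default truth, oil is deliberately the hard
trait: small weather coefficients and a weak genetic main effect put its
attainable R² from a few hundred labeled records well below yield's.
Transfer learning only pays when the target task is genuinely data-scarce
relative to its difficulty — with a strong-signal oil trait, a
from-scratch model matches the pretrained one and the comparison shows
nothing. Per-trait genetic scaling (``trait_geno_scale``) controls this. An optional genotype-by-environment term
(`gxe_scale`) lets families modulate the first causal window's weight by
`1 + gxe_scale · u_family`, `u ~ N(0,1)` clipped to ±2; the default 0
recovers the purely additive model. Trait noise can be set directly
(`noise_sd`) or via a target signal-to-noise ratio: `snr = 3` puts the
ideal predictor's R² ceiling at `snr²/(snr²+1) = 0.9`.

**Missingness.** Oil/protein are removed for whole environments at a time
(environments sampled without replacement until the requested record
fraction is first reached), reproducing the environment-blocked
missingness pattern of cooperative trial networks, at the observed rate of
49.3% of records by default.

## Kinship and clustering

The A matrix uses the classical tabular method
(`A[i,i] = 1 + ½A[sire,dam]`, `A[i,j] = ½(A[j,sire]+A[j,dam])`, unknown
parents contributing 0; parentless genotypes treated as unrelated
founders). An independent gene-dropping Monte-Carlo estimator (simulated
Mendelian allele transmission, 10⁵ replicates) serves as the validation
oracle; the two agree within ±0.02 per entry on random pedigrees.
Genotypes are clustered by K-means (k-means++ init, fixed seed) on the
genotype's kinship row concatenated with its mean yield across
environments, columns standardized. The cluster count is chosen by mean
silhouette over a candidate list, with the full inertia/silhouette table
exposed so a user can override it; on the simulated pedigrees the
procedure recovers the planted families exactly.

## Tokenization

The season is split into consecutive windows of `interval_days`; each
(variable, window) pair is one token whose d = 3 channels are the window
max, min and mean (the final short window aggregates only its real days).
Three context tokens follow: location (standardized latitude/longitude),
genotype cluster and maturity group as categorical codes. For V = 6
variables and P windows, T = 6P + 3 (so 214 days at 14-day windows gives
P = 16, T = 99). Weather channels and location are z-scored with
statistics fitted on the training split only; trait targets are likewise
standardized for training and de-standardized for metric reporting (the
source protocol does not state its normalization; train-split z-scoring
is this package's documented choice). Daily precipitation is
log1p-transformed before window aggregation — without it the standardized
token distribution is dominated by outliers that measurably distort
attention. Category codes reserve 0 for "masked" (its embedding row is
pinned to zero, making a zeroed token a true neutral input) and 1 for
"unseen at inference".

## Model

Tokens are embedded by a shared linear projection `E ∈ R^{3×d'}`; the two
categorical tokens instead use dedicated embedding tables. A learned
positional encoding is added (sinusoidal available by config), followed by
LayerNorm over the embedding dimension, dropout, and N post-norm encoder
blocks (multi-head self-attention + position-wise feedforward, residual
connections, LayerNorm). The final T×d' representations are flattened
into a single linear regression head. The embedding LayerNorm is a
deliberate choice: it equalizes token scale so that attention reflects
content rather than raw magnitude. Positional encodings are initialized
small (0.02) so that early attention is content-driven rather than
position-driven.

Training minimizes MSE on standardized targets with Adam, cosine
learning-rate annealing, batch shuffling, early stopping on validation
loss (default patience 20) and restoration of the best-validation
checkpoint. The full-scale protocol this mirrors used lr 5×10⁻⁶ at batch
16 for up to 100 epochs; at the package's desk scale (~2,000 records) the
defaults are lr 10⁻³, batch 16 (experiments use 64), 100 epochs max.
Everything is plain float32 NumPy with hand-written backprop; gradient
correctness is pinned by finite-difference tests in double precision.

**Transfer.** For the data-scarce traits: `vanilla` trains the
architecture from scratch on the scarce trait; `frozen` copies a
yield-pretrained model and trains only a fresh regression head (the
encoder is verified bit-identical before/after); `finetune` starts from
the pretrained encoder with a fresh head and updates everything.

**Splits.** Record-level random 80/10/10 by seed (the source protocol);
the split is computed before normalization statistics are fitted.
Environment- or year-blocked splits can be built by passing explicit
index triples.

## Baselines

LASSO and SVR-RBF (scikit-learn) consume the flattened token sequence;
one-layer bidirectional RNN and LSTM (NumPy BPTT, last-state concatenation
into a linear head) consume the per-timepoint matrix with context features
broadcast to every step. All baselines share the transformer's exact
splits and the same metric implementation, and select hyperparameters by
validation RMSE over a small grid.

## Interpretability

**Attention importance** of token j is the mean attention j *receives*:
the column mean of each T×T attention map, averaged over heads and layers
and renormalized to sum to 1. (Whether one should average rows or columns
is genuinely ambiguous; row means are identically 1/T by softmax
normalization, so "received" is the only informative direction for this
aggregation.)

**Attributions** are computed in the model's embedded token space along
the straight path from the embedded all-zero token matrix (zero weather
channels, mask code for categorical tokens): integrated gradients
(default 64 steps), GradientSHAP (expected gradients with Gaussian
baselines around the zero-token embedding), and LIME (weighted ridge
regression of predictions on random token keep/drop masks). Per-channel
attributions are pooled by absolute value into one nonnegative score per
token. DeepLIFT is declared as an adapter slot that raises a capability
error — no backend for it exists in this build. Near the zero-token
baseline the embedding LayerNorm makes the path stiff (token variance is
small, gradients large), so the IG integral uses the substitution
α = t² — midpoint nodes concentrate near the baseline with a damping
weight 2t. With that quadrature, completeness (attributions summing to
f(x) − f(baseline)) holds within 1% at 256 steps on trained models.

## Faithfulness

For levels k ∈ {5, 7.5, 10, 15, 25} percent, `m = round(k/100 · T)`
(minimum 1) tokens are masked: the top-m by the explainer's ranking
(*comprehensiveness*) or everything but the top-m (*sufficiency*). Ties
rank by ascending token index; rankings are computed once per sample on
the unperturbed input. The mask is the zero token in standardized space
(≈ channel mean; for category tokens, the pinned-zero embedding row).
Prediction deltas are summarized as MAE and MSE over samples on the trait
scale, and AOPCR is the unweighted mean across levels. A config flag
restricts masking to weather tokens, holding context fixed — the package
uses this for oracle-recovery experiments because the model's single
strongest reliance is legitimately the genotype-cluster token, which the
weather-only oracle by definition never ranks.

## What the synthetic benchmark shows — and what it does not

The standard benchmark is a regional network (50 environments, latitude
36–44°N, 40 genotypes each from a 6-family pedigree), causal windows in
mid-season irradiance (positive) and maximum temperature (negative), G×E
on the irradiance window (`gxe_scale = 1`), SNR 3, and 75% oil/protein
missingness (leaving ≈ 500 labeled records for the transfer experiments).
Two identifiability considerations shaped it:

1. *Causal windows must carry variation not reconstructable from
   elsewhere.* With a wide latitude range and weak within-season
   variability, every weather token proxies every other through the
   shared seasonal/latitude structure, and a model can (correctly) spread
   its reliance — no explainer can then recover the planted windows.
   Raising within-season thermal/radiative variability makes the causal
   window means informative in their own right.
2. *Resolution interacts with identifiability.* Faithfulness and ablation
   experiments run at the 28-day tokenization, where the planted windows
   align with token boundaries and masking them removes the signal;
   attention recovery runs at the 14-day resolution, where per-variable
   attention profiles are finer-grained. At fine resolutions adjacent
   windows are mutually correlated and masked signal partially leaks back
   in through the shoulders — a property of autocorrelated weather, not
   of any particular explainer.

Passing tests therefore show that the pipeline recovers *planted,
identifiable* structure under controlled conditions. They do not show
that real trial data has such structure, that attention margins of this
size are meaningful on real data, or that the generator's distributions
match real soybean trait distributions or US geography (explicit
non-goals). Attention and attribution scores are model-reliance
measures, correlational rather than causal.

## Numerical choices

- float32 parameters and activations; attention softmax is max-shifted.
- LayerNorm ε = 10⁻⁵; degenerate (zero-variance) normalization channels
  fall back to sd 1 so standardized values sit at 0.
- K-means uses 10 restarts at fixed seed; silhouette undefined at k = 1
  or k = n is reported as NaN and skipped in selection.
- Zero-variance truth leaves R² undefined (reported as missing, never
  0/∞); RMSE/MAE are always defined.
- Early stopping counts non-improving epochs (tolerance 10⁻⁷) from the
  best epoch; max_epochs = 0 returns the initialized model.
- Gene dropping vectorizes replicates; founder alleles are globally
  unique labels, so identity-by-descent is exact label equality.
- Problem sizes in tests (2,000-record studies, 40-epoch training runs,
  10⁵ gene-dropping replicates) are chosen so the full suite documents
  the science at laptop scale; the same code runs larger studies by
  changing the `Scenario`.

## Known limitations

- The recurrent baselines are deliberately small one-layer models; they
  are comparison points, not tuned competitors.
- LIME on long sequences (T ≈ 100) with the default 256 mask samples is a
  coarse surrogate; its rankings are noticeably noisier than the gradient
  methods', which the faithfulness tables reflect.
- The "program of origin" covariate sometimes recorded in cooperative
  trials has no specified encoding and is omitted from clustering.
- Attention-mean margins on desk-scale models are small (≈ 2–5% above the
  uniform 1/T baseline); the package asserts their *sign* across seeds,
  not their magnitude.
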