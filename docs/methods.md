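# Methods

`ricerisk` grades and forecasts the dietary heavy-metal safety risk of rice
at province-week resolution. This note documents the models, the default
parameters and the design decisions, in the order the pipeline runs.

## Risk indicators

One province-week of laboratory samples is summarised by three indicators.
Let `C_j` be the weekly within-province mean concentration of metal
`j ∈ {Cd, Cr, As(inorganic)}` (mg/kg) after non-detect handling, `S_j` the
national limit, `F50` the province's mean daily rice consumption (kg/d) and
`W = 60 kg` the reference adult body weight.

* **Single-factor index** `P_j = C_j / S_j`, with limits
  `S = (0.2, 1.0, 0.2)` mg/kg for Cd, Cr, As.
* **NIPI** (Nemerow integrated pollution index)
  `sqrt((max_j P_j² + mean_j P_j²)/2)` — emphasises the worst metal while
  retaining the average; values above 1 indicate contamination.
* **THQ** (target hazard quotient) `Σ_j F50·C_j / (RfD_j·W)` with oral
  reference doses `RfD = (0.001, 0.003, 0.0003)` mg/(kg·d). Toxicity is
  treated as additive; no synergy or antagonism is modelled. THQ ≤ 1 is
  read as low noncarcinogenic risk.
* **TCR** (total carcinogenic risk) `Σ_j EF·ED·CSF_j·EDI_j / ATC` with
  `EDI_j = F50·C_j/W`, cancer slope factors `CSF = (6.3, 0.5, 1.5)`
  kg·d/mg, exposure frequency `EF = 365` d/y, exposure duration
  `ED = 70` y and averaging time `ATC = 365·70` d. With these defaults the
  prefactor cancels exactly, so `TCR = Σ_j CSF_j·EDI_j`; the factored form
  is kept so non-default exposure scenarios remain expressible.

**Non-detects.** Measurements below a metal's limit of detection are
imputed at LOD/2 before averaging — the standard treatment when the
non-detect fraction is well below 60%. Default LODs are 0.01 (Cd),
0.05 (Cr) and 0.01 (As) mg/kg; they are configuration, not constants,
because they are instrument properties.

**Aggregation choices.** `C_j` is the weekly within-province *mean* of the
LOD-substituted samples; the max in NIPI is taken across metals of these
weekly means, not across individual samples (one indicator triplet per
province-week is the modelling unit). Weeks in which a province has no
samples carry the last available triplet forward — the forecaster needs a
gapless axis — and are flagged `gap_filled`; leading gaps take the first
available triplet. All arithmetic is double precision with no intermediate
rounding.

## Risk grading

The (NIPI, THQ, TCR) points of all province-weeks are min-max normalised
per coordinate (`(x − min)/(max − min)`, fitted once on the grading data;
transform mode does not clip out-of-range values). K-medoids is used
rather than k-means because surveillance data contain isolated extreme
province-weeks and medoids — which are dataset points — are robust to
them. The fitting loop is randomised swap search: assign points to the
nearest medoid (Euclidean; ties to the lowest medoid index), propose a
random (medoid, non-medoid) swap, accept iff the summed distance strictly
decreases, and stop after `200·k` consecutive rejections. The best of 20
independent restarts is kept; all randomness derives from one master seed,
so results are reproducible. Swap evaluation is incremental (nearest and
second-nearest distances are cached), making a proposal O(n).

The cluster count is selected from k = 2…7 by the mean silhouette
coefficient `s = (b − a)/max(a, b)` (singleton clusters score 0),
computed on the normalised coordinates. The chosen medoids are ordered by
Euclidean distance from the origin; for k = 3 the order is read as
Low < Medium < High, since points near the origin have uniformly small
indicators. `RiskGradingModel.fit()` returns a results object carrying the
level space (centers in normalised and original units), the silhouette
table, the per-point assignment and a `summary()`.

## Forecasting

One forecaster is fitted per indicator, pooled over provinces with a
learned province embedding (pooling shares the seasonal signal across
provinces; a per-province mode would need far more history). Each
province series is standardised using training-week statistics only.

The network is an encoder–decoder with ProbSparse self-attention:

* **Embedding** — value projection to width `d`, plus sinusoidal local
  positional encoding, plus a learned week-of-year embedding (period 53,
  the annual period of the weekly axis), plus the province embedding.
* **ProbSparse attention** — the sparsity measure of query `q_i` is
  `M(q_i, K) = ln Σ_j exp(q_i·k_j/√d) − (1/L_K) Σ_j q_i·k_j/√d`, computed
  exactly with a max-shifted log-sum-exp (at these sequence lengths the
  sampled approximation used at long-sequence scale buys nothing). Only
  the `u = ⌈c·ln L_Q⌉` queries with the largest measure receive softmax
  attention `softmax(Q̄Kᵀ/√d)V`; the remaining rows fall back to the mean
  of V — the cumulative mean up to the row under a causal mask. Selection
  is not differentiated through.
* **Encoder** — the main stack alternates attention layers (each wrapped
  in residual + LayerNorm, followed by a position-wise ELU feed-forward
  block) with distillation layers (kernel-3 same-padded convolution, ELU,
  stride-2 max-pool halving the length to ⌈L/2⌉); there is one distillation
  fewer than attention layers. A replica stack with one fewer layer
  consumes the last half of the input; stack outputs are concatenated
  along time into the feature map.
* **Decoder** — input is the last `label_length` known weeks followed by
  zero placeholders for the horizon. Masked (causal) ProbSparse
  self-attention, full multi-head cross-attention onto the feature map,
  then a position-wise head produce all horizon steps in a single forward
  pass — no autoregressive loop.

Defaults: input 36 weeks, label 12, horizon 21, `d = 32`, 4 heads,
`c = 1`, 2 encoder layers + 1 distillation (main stack), feed-forward
width 64, dropout 0.05, Adam at 1e-3, batch 64, MSE on the horizon slice,
25 epochs. Training loss on default-condition data plateaus around epoch
15, so 25 epochs is comfortable convergence at desk scale. The network
runs on the package's own numpy reverse-mode autodiff engine
(`ricerisk.autodiff`); every op's gradient is tested against central
finite differences, and everything is deterministic under a fixed seed.

Forecast weeks are assigned to risk levels by normalising the predicted
triplet with the stored grading parameters and taking the nearest center
(ties toward the lower level). Forecast quality is scored by RMSE/MAE per
indicator and one-vs-rest precision/recall/F1 per level (in percent;
zero-denominator ratios report 0 with a warning). The reference for level
evaluation is the nearest-center assignment of the *true* indicator
triplets, so grading and evaluation share one geometry; the generator's
latent labels are reserved for recovery experiments. A persistence
baseline (repeat the last observed value across the horizon) anchors the
comparison.

## Synthetic data

The generator emulates national market-surveillance sampling: per
province-week, `n` samples per metal drawn lognormally, left-censored at
the LOD (stored at the LOD and flagged), with

* province baseline offsets (log-sd 0.1),
* seasonal elevation (×1.25) in the new-rice-market weeks 24–44, 77–97
  and 130–150 of the 159-week axis (annual period 53), and
* latent low/medium/high regimes assigned in contiguous 53-week blocks
  per province with scale multipliers (1, 8, 30); the block layout makes
  ~60% of provinces low throughout, ~25% mixing in medium and ~15%
  carrying high blocks, reproducing the strong class imbalance of
  surveillance data.

Defaults: 20 provinces × 159 weeks × 57 samples — about 181k samples,
the scale of three years of national sampling. Baseline log-means
(−3.7, −2.6, −3.5 for Cd, Cr, As) put typical concentrations well below
the limits, and with log-sd 0.5 give non-detect fractions of roughly
3.5% (Cd), 21% (Cr) and 1.4% (As) — comfortably inside the regime where
LOD/2 imputation is appropriate. Consumption per province is uniform on
(0.2, 0.3) kg/d: deliberately narrower than the real north–south spread
of rice consumption in China, so that the latent contamination regimes,
not consumption heterogeneity, dominate the geometry of the THQ/TCR
coordinates — the generator's purpose is a risk space whose level
structure is recoverable, which is what the grading stage is tested
against. The returned regime map is ground truth for recovery tests only.

What the generator does **not** emulate: within-province spatial
heterogeneity (a province-week is exchangeable samples), reporting delays,
changing provincial panels, metal-specific seasonal phases, regulatory
interventions, and real consumption heterogeneity (see above). Passing
the recovery tests therefore shows the pipeline recovers the structure it
assumes, not that real surveillance data satisfy those assumptions.

## Numerical and degenerate-input conventions

* Min-max normalisation errors out when an indicator is constant.
* `kmedoids` requires k ≤ n; n = k yields zero cost with every point its
  own medoid. Assignment ties break to the lowest medoid index.
* Silhouette requires ≥ 2 non-empty clusters; singleton points score 0.
* Attention: `u` is clamped to [1, L_Q]; with u = L_Q ProbSparse equals
  dense attention (tested to 1e-5). Causal self-attention requires
  L_Q = L_K.
* Forecaster: series shorter than input + horizon before the split error
  out; standardisation guards zero variance at 1e-8.
* Per-province standardisation inverts exactly (affine), so constant
  series round-trip to the constant.

## Problem sizes

Default verification runs use the full default conditions (20 provinces ×
159 weeks, split at week 138, horizon 21); component tests use smaller
instances (≤ 10 points for exhaustive clustering comparisons, L = 8 for
dense-attention oracles, 8 provinces × 54 weeks for model-selection
replicates). These sizes are the package's test design; the library
itself has no hard-coded scale.

## Known limitations

* The national surveillance dataset this kind of analysis targets is
  access-restricted; all quantitative results here are computed on
  synthetic data with known structure, and the generator's stylisations
  (above) bound what they show.
* Persistence is the only built-in baseline; recurrent or full-attention
  comparison models are out of scope.
* The forecaster is univariate per indicator (three independent models);
  cross-indicator dependence is not exploited.
* Mercury and age-stratified exposure are out of scope.
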