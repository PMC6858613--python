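# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `glucoforecast`.

## Forecasting model

The forecaster predicts tomorrow's glucose (mg/dL) from a lookback window
(default 1 day) of six daily features: calories consumed, fat (g),
carbohydrates (g), calories burned, weight (lbs), and glucose. One LSTM
layer is unrolled over the window; dropout is applied to the final hidden
vector during training only; a one-hidden-layer ReLU feed-forward head emits
the scalar prediction on the scaled target.

The cell uses sigmoid activations for all four internal units — forget gate,
external input gate, candidate, and output gate — with the hidden output
`h = tanh(s) ⊙ q`. Both sigmoid and tanh candidate conventions exist in the
literature; the sigmoid-throughout form is used here, and because
`|tanh| ≤ 1` and `0 < q < 1`, hidden activations always satisfy `|h| ≤ 1`
(asserted by a property test). The forward pass, backpropagation through
time, and the Adam optimizer are written directly in NumPy: the network is
small (≤ 60 units, ≤ ~200 training windows per patient), so full-batch
training is faster than any framework overhead, and the implementation can
be verified mechanically — the test suite checks the cell against an
independent scalar implementation to 1e−10 and the analytic gradient against
central finite differences to 1e−4 relative.

Training choices not pinned down by the problem itself: Adam with learning
rate 1e−3, 200 epochs, full batch, seeded initialization with small uniform
weights (scale 1/√fan-in), zero biases except the forget-gate bias at 1.
The epoch with the best validation RMSE is retained. Validation RMSE is
reported in mg/dL (an affine rescaling of the scaled-space RMSE, so epoch
selection is unaffected). The number of LSTM layers is a config option
(default 1).

## Preprocessing

* **Imputation**: last observation carried forward, per feature. The rule is
  undefined at the head of a series, where nothing precedes the gap; the
  first observation is back-filled there so the series keeps its length.
  A feature with no observations at all is an error naming the feature and
  patient. Imputation is idempotent and preserves the observed mask for
  diagnostics.
* **Splitting**: contiguous chronological blocks proportional to 120:30:30.
  Validation and test each get `round(n/6)` days (ties up), training the
  remainder: 180 → (120, 30, 30), 41 → (27, 7, 7), 6 → (4, 1, 1). A
  consequence of nearest-integer rounding is that the training block can
  shrink by one day when the rounded sixth steps up (8 → (6,1,1) but
  9 → (5,2,2)); validation and test sizes are monotone in series length.
* **Scaling**: per-feature min-max onto [−1, 1], fitted **on training rows
  only** to avoid leakage (a test asserts that perturbing test rows leaves
  the fitted parameters bit-identical). Validation/test values may fall
  outside [−1, 1] and are never clipped. A feature constant over the
  training block is an error. Per-patient scaling is the default everywhere,
  including the transfer datasets, since all patients then live on a common
  [−1, 1] scale; pooled scaling would let high-glucose patients dominate.
* **Windows**: targets never cross split boundaries; validation and test
  windows may use up to `lookback` days of context from the preceding split,
  mirroring deployment where yesterday's data is always available.
* **Outliers**: glucose readings outside [40, 600] mg/dL are flagged and
  optionally winsorized; the default is flag-only, since no principled rule
  exists for self-reported data.

## Transfer learning

Both strategies pretrain, then fine-tune on the target patient's own
training windows with all layers unfrozen and the learning rate reduced
tenfold (a standard fine-tuning heuristic; the reduction preserves the
pretrained prior while the small target dataset personalizes it).

* `all`: the pretraining pool is every patient's training windows, target
  included, unweighted.
* `dtw`: donor similarity is the dynamic-time-warping distance between the
  imputed, scaled training-block glucose of target and donor — scaling
  prevents mere level offsets from dominating the comparison. DTW uses
  absolute-difference local cost, full window (no Sakoe–Chiba band), and
  boundary-matched monotone paths; it is symmetric and nonnegative but not a
  metric (no triangle inequality), and nothing here relies on one. Distances
  map to sampling weights by `w_j ∝ 1/(d_j + ε)` with
  `ε = 1e−6·max(d) + 1e−12` — inverse distance was chosen over a softmax to
  avoid a temperature hyperparameter. The pretraining set draws
  `120 × n_donors` windows (with replacement) from donors, donor chosen by
  weight, window uniform within donor.

Pretraining selects its final parameters by training loss (no validation
set exists for the pooled data that would not leak target information);
fine-tuning selects by the target's validation RMSE. With zero target
training windows the pretrained parameters are returned unchanged, and
strategy `none` is byte-identical to plain training on the target.

## Hyperparameter optimization

The three tuned hyperparameters are dropout rate, LSTM units, and dense
units, over lower bounds (0.10, 5, 5) and upper bounds (0.45, 60, 40) with
unit changes (0.01, 1, 1). Counting `(upper − lower)/step` per dimension
(no +1), the full grid has 35·55·35 = 67,375 combinations.

The optimizer evaluates a 15-point Latin hypercube design (one sample per
equal-probability stratum per dimension; integer dimensions are rounded to
the nearest step *inside* the source stratum, re-placed when plain rounding
would cross a boundary), fits a Gaussian process — anisotropic squared-
exponential kernel plus a small white-noise floor, outputs standardized,
kernel scales by marginal-likelihood maximization (scikit-learn's
`GaussianProcessRegressor`) — and proposes the next setting by maximizing
expected improvement over the discretized space with ~2k random candidates
plus a ±3-step neighborhood sweep around the incumbent. For minimization,
with `z = (incumbent − μ)/σ`: `EI = (incumbent − μ)Φ(z) + σφ(z)`, zero when
`σ = 0`. The loop stops when a proposed evaluation fails to improve the
incumbent RMSE by a relative 1e−3 (patience 1, both configurable) or the
budget is exhausted. Each setting gets a single seeded training run; a
failing objective is recorded and excluded from the surrogate. The audit
trail (setting, RMSE, incumbent per iteration) is exportable as CSV.

## Baselines

KNN (k = 3, unweighted Euclidean on scaled features; distance ties resolve
to the earlier training index, i.e. the earlier day), ridge regression
(unpenalized intercept via centering), Gaussian kernel ridge
(`k(a,b) = exp(−γ‖a−b‖²)`), a feed-forward net on the flattened window with
validation-selected epoch, and a last-3-days moving average. The moving
average predicts from the last `n` *observed* glucose values before the
target day, using a shortened window when fewer exist. Ridge/kernel-ridge
penalties and the bandwidth are grid-tuned on the validation split. The four
ML baselines stand on scikit-learn estimators behind a uniform fit/predict
surface; all consume exactly the windows the LSTM consumes.

## Clinical evaluation

Clarke Error Grid zones follow the canonical 1987 piecewise rules, evaluated
in the order A, E, C, D, else B, with boundary equalities inclusive toward
the zone listed first (so a pair on the ±20% edge is A, and a pair with
reference 180 and prediction 70 is E). For references above 70 mg/dL, zone A
coincides exactly with the ±20% band — a cross-metric consistency property
the suite tests. The pooled zone table concatenates all patients' test pairs
per method before computing percentages (reported to 2 decimals); per-patient
±10% accuracy is the share of test days within 10% of the reference. A
method failing on a patient leaves a missing cell; the comparison continues.

## Synthetic cohort generator

No public dataset exists for this setting, so the generator produces what
the pipeline's premise assumes: yesterday's lifestyle predicting today's
glucose. Glucose follows

```
g_t = b + ρ(g_{t−1} − b) + β_c(carb_{t−1} − μ_c) + β_e(burned_{t−1} − μ_e)
        + β_w(w_{t−1} − w_0) + ε_t,   ε_t ~ N(0, σ²)
```

with covariate terms mean-centered so that the baseline `b` is directly the
stationary mean — parameter defaults are chosen so simulated means land in
[100, 200] mg/dL and weights in [140, 360] lbs, the envelope typical of
overweight/obese type-2-diabetes cohorts. Defaults: ρ ∈ (0.35, 0.7),
β_c ∈ (0.08, 0.2) mg/dL per g, β_e ∈ (−0.05, −0.01) mg/dL per kcal,
σ ∈ (6, 14) mg/dL, series length 150–190 days, glucose missingness 8–35%
(the scarce patient: 40 days, 40%). Lifestyle covariates are truncated
normals (e.g. carbs ~ N(220, 40) g); weight is a slow random walk with
drift, clipped to [100, 400] lbs, with a weak optional coupling into
glucose (β_w, default 0.1 mg/dL per lb of deviation from the starting
weight). Missingness is independent per cell by default; a burst mode
(two-state Markov chain with mean run length 5, calibrated to the same
marginal rate) emulates patients who stop logging for stretches.

Patients are assigned round-robin to archetypes, so several patients share
dynamics and similarity-weighted transfer has true signal to find. What the
generator does **not** emulate: meal-timing and intra-day physiology,
medication effects, measurement-time variability, informative missingness
(logging lapses correlated with glucose excursions), and reporting biases of
self-logged food diaries. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes when that structure is present —
not that the same accuracy holds on real self-monitoring data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the method comparison on a
10-patient, 3-archetype cohort with the default 150–190-day series, the
transfer study as 10 seeded replicates of the scarce-patient cohort, and
the optimizer benchmarks on 2-D quadratics with ≤ 40 evaluations — sizes
at which every result above is reproduced in well under a minute per suite
on a single CPU, chosen as the package's standard demonstration scale.
Scaled RMSE and mg/dL RMSE are interchangeable for model selection (affine
relation); scale/inverse-scale round-trips are exact to < 1e−9; all
randomness flows from explicit seeds through `numpy.random.default_rng`,
making every simulation, training run, sampling step and optimization
bit-reproducible.

## Known limitations

* One-day-ahead, one-reading-per-day forecasting only; no CGM-style
  intra-day modeling, no multi-step horizons.
* LOCF imputation biases toward flat trajectories over long gaps; patients
  with long adjacent missing runs are exactly the ones where the moving
  average can beat the learned models.
* The GP surrogate treats integer dimensions by continuous relaxation and
  rounding, which can propose already-evaluated settings near convergence
  (handled by deduplication, but it wastes proposals in tiny spaces).
* The synthetic generator's linear-Gaussian dynamics are an idealization;
  nonlinear glycemic responses (e.g. threshold effects of exercise) are out
  of scope.
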