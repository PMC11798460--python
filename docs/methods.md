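# Methods

This document defines every computation in the pipeline precisely enough to
reimplement it, states the default parameters, and lists known limitations.

## 1. Data model

A *crop panel* is a long-format table with one row per (region, time-step):
key columns `region_id` (string code) and `t` (integer), numeric
agro-environmental features, optional categorical features, a `yield` value
and an optional binary `label` (1 = minority class, conventionally low-yield
region-years).

## 2. Synthetic panel generator

Each numeric feature is a stationary AR(1) series per region with marginal
mean/sd and autocorrelation `ar1` (default 0.5). A latent yield is

```
yield = 5.0 + Σ_f w_f · x_f + region_offset + N(0, noise_sd²)
```

Labels are `yield < quantile(class_rule)`; the generator then flips the rows
nearest the threshold so the minority count matches `minority_fraction`
within one row. Missingness is injected MCAR on numeric feature cells only;
outliers shift randomly chosen cells by ±`magnitude_sd` column standard
deviations (positions returned for auditing).

Two benchmark fixtures:

* `signal_spec` — 100 regions × 20 steps, 3 informative features with
  per-feature standardized effect 2.0 (weight 2.0, unit feature sd,
  `noise_sd = 1`) + 7 zero-weight noise features, minority fraction 0.2.
* `null_spec` — 30 regions × 10 steps, 5 features, all weights zero,
  minority fraction 0.5 (so the majority rate equals chance and a two-sided
  at-chance test is meaningful).

## 3. Preprocessing

Fitted on training data only; parameters serialize to JSON.

* **Imputation** — per-region linear interpolation over `t`
  (`numpy.interp`); edge gaps take the nearest observed value; a region with
  a feature entirely missing falls back to the global training median (with
  a warning).
* **Outliers** — winsorization to the 1.5×IQR fences computed from observed
  raw training values.
* **Scaling** — min-max to [0, 1] using post-impute/winsorize training
  min/max; a constant feature is flagged `degenerate` and maps to 0; unseen
  data is *not* clipped (out-of-range inputs stay visible).
* **Categoricals** — one-hot columns named `feature=level`; unseen levels
  encode as all-zero with a warning.
* **Temporal alignment** — `align_temporal` outer-joins panels from
  different sources onto the union (region, t) grid and forward-fills per
  region.

## 4. ADASYN balancing

For minority count `N_min` and majority count `N_maj` (imbalance ratio
`r = N_maj / N_min`):

1. For each minority point `x_i`, find its `k = 5` nearest neighbors in the
   whole training set (Euclidean distance, self excluded, ties broken toward
   the lower index); `d_i` = majority neighbors among them, `r_i = d_i / k`.
2. Normalize `r̂_i = r_i / Σ r_i` (uniform if all zero) and allocate
   `G_i = r̂_i · G` synthetic samples, `G = N_maj − N_min`, using
   largest-remainder rounding so `Σ G_i = G` exactly.
3. Each synthetic row is `x_i + δ (x_nn − x_i)` with `δ ~ U(0, 1)` and
   `x_nn` one of the `k` nearest *minority* neighbors of `x_i`.

Every synthetic row carries provenance `(parent index, neighbor index, δ)`
sufficient to reconstruct it exactly. The difficulty statistics
`(d_i, G_i)` are deterministic given the data; only the draws depend on the
seed.

## 5. Feature engineering

Runs on the *window-end* (most recent step) slice of the balanced training
windows, so importances refer to the original preprocessed features.

1. **SVM importance.** A linear SVM minimizes the primal hinge objective
   `½‖W‖² + C Σ max(0, 1 − y(Wx + b))` (`C = 1`). It is solved by gradient
   descent on a Huberized (smoothed) hinge with an annealed smoothing
   parameter (μ from 0.5 down to 1e-6) and Armijo backtracking line search,
   tracking the best iterate, so the reported objective trace is
   non-increasing. Importance of feature `j` is `|W_j|`.
2. **Top-m selection** (default: keep all) by importance, ties toward the
   lower index.
3. **NGD pruning.** Features are binarized by `value > per-feature median`.
   For occurrence counts `f_i, f_j`, joint count `f_ij` and sample count `N`:

   ```
   NGD(i, j) = [max(log f_i, log f_j) − log f_ij] / [log N − min(log f_i, log f_j)]
   ```

   Sentinels: any zero count → 1.0 (unrelated); zero denominator → 0.0 iff
   `f_ij = f_i = f_j` (identical), else 1.0. Pairs with `NGD < τ`
   (default τ = 0.1) are scanned in ascending NGD order and the
   lower-importance member is dropped (skipped if the other member was
   already dropped).
4. **Rising-Star ranking.** The SVM is refit on `T = 5` chronologically
   expanding windows of the training data; for each kept feature,
   `P` = mean |weight| over the refits, `R` = |weight| in the latest refit,
   and the score is `S = αP + βR` with `α = β = 0.5`. Features are ranked by
   descending `S`.

## 6. Sequence models

Both members consume sliding windows of length `L = 4` per region (label and
yield taken at the window end). They are built on a small reverse-mode
autodiff core (`cropvote.autodiff`) and trained with Adam
(lr 0.01, batch 64, 60 epochs, seeded shuffling).

* **Bi-GRU.** Gate equations per step (the update gate `F` interpolates
  between the previous state and the candidate):

  ```
  F_t = σ(W_F [h_{t−1}, x_t] + b_F)
  r_t = σ(W_r [h_{t−1}, x_t] + b_r)
  h̃_t = tanh(W_c [r_t ⊙ h_{t−1}, x_t] + b_c)
  h_t = (1 − F_t) ⊙ h_{t−1} + F_t ⊙ h̃_t
  ```

  The forward pass's final state and the backward pass's final state are
  concatenated (hidden size 16 each) and fed to a softmax head.
* **1-D CNN.** Each convolution layer slides width-`w` windows over the
  sequence, flattens them and applies a weight matrix + ReLU; pooling takes
  the elementwise maximum over non-overlapping groups. Default for window
  length ≥ 4: two layers of 8 filters, width 2, the second followed by
  max-pool 2, then a dense layer (size 16) and softmax.

**Vote (ensemble fusion).** Hard majority over member labels. On a tie, the
member probability vectors are summed and the argmax wins; a residual tie
falls to the lowest class index. The prediction records the tally, the
member labels and whether a tie occurred. An optional regression route
trains the same architectures with an MSE head on min-max-scaled yield and
reports MAE/MSE/RMSE of the member-mean prediction.

## 7. Leakage-safe evaluation

* **Split before balance.** Regions (never rows) are assigned to train/test,
  so no temporal window straddles the split; ADASYN runs on training windows
  only; the test panel's SHA-256 hash is recorded at split time.
* **Audit.** Every run checks: train/test region disjointness, bit-identity
  of the test panel against its recorded hash, and that every ADASYN
  provenance index points into the training windows.
* **Metrics.** Accuracy, precision, recall, F1 (class 1 positive);
  zero-denominator cases return 0 with an explicit flag.
* **k-fold CV.** Region-grouped folds (permuted, `array_split`), the same
  preprocessing/balancing discipline inside every fold, per-fold reseeded
  sub-configs. `summarize_cv` reports per-fold, mean and sd accuracy.

One global seed expands deterministically into per-stage sub-seeds
(`PipelineConfig.reseeded`), so a YAML config plus a seed reproduces a run
exactly.

## 8. Numerical choices

* The SVM solver uses an annealed smoothed hinge rather than a raw
  subgradient method: the objective is piecewise linear and subgradient
  steps stall at kinks; the annealed smooth problems converge to the hinge
  optimum (verified against a dense parameter-grid oracle and an
  independent solver in the test suite).
* The autodiff core supports exactly the operations the models need
  (matmul, elementwise arithmetic, sigmoid/tanh/ReLU, maximum, concat,
  fused softmax-cross-entropy and MSE); gradients are validated against
  finite differences in the tests.
* `maximum` routes gradients to the first argument on exact ties; k-NN and
  ranking ties break toward the lower index — all deterministic.

## 9. Limitations

* Binary classification only; the vote generalizes to more classes but the
  generator and metrics assume two.
* The GRU/CNN members are small, CPU-only and batch-trained; they are sized
  for panels of thousands of windows, not millions.
* ADASYN interpolates in the flattened window space; with very few minority
  samples (< 2) it refuses to run rather than fabricate structure.
* The SVM non-convergence warning is a heuristic (final annealing stage
  still improving); on large balanced panels it can fire even when the
  objective is within a fraction of a percent of optimal.
* The regression route trains on original (pre-balance) windows, since
  synthetic rows carry no yield; its errors are reported on the
  min-max-scaled axis.
* NGD binarization by the median discards within-half variation; features
  whose relevance lives in the tails may be judged unrelated.
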