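# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic benchmarks establish.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Model and assumptions

The pipeline assumes a binary diagnostic label and V ≥ 1 views of the same
subjects, each view a subjects × features matrix of Fisher-z Pearson
connectivity values (or any real-valued features).  Views must share the
subject universe; alignment is by subject identifier, never by row order.

**Connectivity construction.**  Pearson correlation across timepoints,
Fisher z (arctanh), strictly upper triangle in row-major order with 0-based
indices.  Assumes stationary series with nonzero variance per region; a
zero-variance region is a hard error, because silently imputing a
correlation of 0 (or NaN→0) would bias feature selection toward or away
from that region's edges.  |r| is clipped to 1 − 1e−7 before arctanh so
that degenerate, perfectly correlated series stay finite.

**Selection.**  The view-weighted lasso is solved by ISTA with fixed step
1/L, L = σ₁(X)²/N estimated by power iteration (tolerance 1e−8; any
overestimate preserves monotone descent).  Starting point ω₀ = 0;
convergence when max|Δω| < 1e−7 or 5000 iterations.  The regression target
encodes the two classes as ±1 and is mean-centred, and each feature column
is z-scored on the training rows (both configurable); with centred y and X
no intercept is needed.  ISTA produces exact zeros, so the support
threshold 1e−8 only guards float noise.  Exactly two penalty groups exist
regardless of V: the primary view (weight a₁) and all auxiliary views
pooled (a₂ = 1 − a₁).  An empty primary support falls back to the top-10
|ω| positions so later stages never receive a zero-width view.

**Penalty strength λ.**  No principled universal value exists for the
weighted problem, and λ trades false positives against misses.  The default
λ = 1.0 is derived once from the lasso universal-threshold heuristic: with
z-scored features and a ±1 target, coefficients below σ√(2 ln D / N) are
indistinguishable from noise; at the default benchmark size (D = 376,
N = 200) that is ≈ 0.24, and with the primary weight a₁ = 0.2 the primary
view's effective threshold λ·a₁ matches it at λ ≈ 1.  Users should sweep λ
for their own data; the a₁ sweep harness accepts any λ.

**Encoders.**  Greedy layer-wise pretraining trains each layer, in order,
as a one-hidden-layer autoencoder (tanh encoder, linear decoder, full-batch
Adam at 1e−3 for 50 epochs by default) reconstructing that layer's input;
the decoder is discarded.  Fine-tuning then optimises all parameters under
the full supervised loss.  Pretraining can be disabled.  Activation is tanh
throughout: bounded activations keep the per-sample mean/variance
statistics inside the NCC regulariser well-scaled.  Initialisation is
fan-in-scaled uniform from a seeded generator; every training path is
bit-reproducible given its seed.

**Fusion.**  The fusion layer replaces hidden layer `position` (default 3,
the final hidden layer, the configuration that performed best in the
fuse-position ablation).  Per-view maps are linear with no bias or
activation, so the invariant z = Σ_v u_v holds exactly; layers after the
fusion position are shared across views.  The NCC is computed per sample
over the K fused coordinates with sample standard deviations (ddof = 1) and
averaged over the batch; a formulation without the square root in the
denominator would not be bounded by [−1, 1], so the standard Pearson form
is used.  The alignment sum runs over consecutive view pairs v = 1..V−1 by
default (`all_pairs` available); with V = 1 it is identically zero.
Per-sample rows with zero variance contribute 0 with zero gradient — they
occur routinely in the first training steps and vanish as the maps spread.

**Classifier and training.**  γ = 1.0, margin m = 1.0, λ₁ = 0.5, λ₂ = 0.1
by default; none of these have canonical values and all are config-exposed.
λ₂ is kept small because the alignment term is bounded (|L_MV| ≤ V−1) but
its gradient can dominate early, when distances — and hence the DCE
gradients — are still small.  Prototypes are class means of the current
network outputs, recomputed at each epoch start and treated as constants
within the epoch: recomputing per batch at batch size 96 would make the
class means noisy, and letting gradients flow into the means couples every
instance's loss to every other's.  Probabilities use max-shifted
exponentials; −log P clamps P at 1e−12.  Distance ties in prediction break
toward the lower class index (deterministic, documented, only reachable on
degenerate inputs).  Best-validation-accuracy checkpointing over a default
budget of 300 epochs; epoch 0 means "return the initial state".

**Cross-validation.**  "5-fold with a 3:1:1 split" is realised by one
shuffle into five near-equal folds, round r testing on fold r, validating
on fold (r+1) mod 5 and training on the rest — test folds are disjoint and
cover all subjects, and each round's ratio is 3:1:1.  Selection, feature
scaling and training are all fitted per round on training rows only.
Reported numbers are always test-fold means, not best-validation values.
The positive class for SEN/PPV is the patient group (label 1 in the
synthetic data).  A metric with a zero denominator is flagged undefined
(`None`), never coerced to 0 or 100.

## Synthetic generator: what it does and does not establish

`generate_multiview` draws feature noise i.i.d. N(0, noise_sd²), shifts s
planted edges per view by ±effect/2 by class, and adds one per-subject
latent factor to the shared subset of planted edges in every view —
emulating sparse discriminative connectivity with partially shared
cross-view structure.  Defaults: N = 200 balanced subjects, views of
190/66/120 features (20/12/16 regions), s = 10, shared_fraction = 0.5,
effect = noise_sd = latent_sd = 1 (per-feature signal-to-noise 1.0).  The
high-separation classification benchmark raises effect to 5.0.

`generate_timeseries` instead draws multivariate normal ROI series whose
population correlation on planted region pairs differs by class (0.6 vs
0.0 by default, T = 200), with automatic shrinkage toward the identity if
the target matrix is not positive definite; it exercises the connectivity
construction end to end at Fisher-z sampling error ≈ 1/√(T−3).

Neither path simulates fMRI autocorrelation, site/scanner effects, motion,
or realistic between-edge correlation structure.  A green synthetic result
establishes that the implementation recovers planted sparse signal and
separable classes under the stated noise model — it says nothing about
accuracy on real cohorts, where effect sizes are far smaller and
confounders dominate.

## Design choices made where the design was open

- **No deep-learning framework.**  The network is small and dense; NumPy
  with hand-written backpropagation keeps the dependency surface minimal,
  and every gradient path is validated against central finite differences
  (tolerance 1e−4) in the test suite.
- **Selection refit per fold.**  Leak-free by construction; fitting
  selection once on all data would inflate test metrics.
- **Alignment term only during fine-tuning.**  Layer-wise pretraining is
  per-view reconstruction; the cross-view term enters with the supervised
  loss.
- **Library vs CLI.**  The package is a library with narrative example
  scripts; runs are configured through `mvconn.config.RunConfig` (YAML,
  unknown keys rejected, effective config echoed), and a master seed fans
  out to per-stage seeds by fixed offsets (`mvconn.config.derive_seed`).
- **Test-scale specs are first-class.**  Widths such as (16, 8, 8) with
  K = 8 run the full pipeline in seconds; the default widths
  (1000, 100, 100) with K = 100 remain the production configuration.

## Known limitations

- Binary classification only in the experiment harness (the loss and head
  are implemented for general C, but splits and metrics assume two
  classes).
- Plain ISTA, no FISTA acceleration and no cross-validated λ path; large
  D with small λ can need many iterations.
- The auxiliary views share a single penalty weight; per-view auxiliary
  weights are not supported.
- `generate_timeseries` plants pairwise correlations independently; it does
  not guarantee a realistic full covariance spectrum.
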